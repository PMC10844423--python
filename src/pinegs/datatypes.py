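"""Shared in-memory containers for the genomic-selection pipeline.

Conventions used throughout the package:

* Genotypes are biallelic SNP dosages of the minor (alternate) allele coded
  0/1/2, stored as ``float32`` with ``NaN`` marking missing calls.
* Phenotypes live in a long-format :class:`pandas.DataFrame` with columns
  ``id, site, block, family`` plus one column per trait
  (``dbh, height, straightness, volume``).
* Pedigrees are individual/dam/sire triples; ``"0"`` denotes an unknown
  parent (open pollination leaves every sire unrecorded).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical trait column order in phenotype tables
TRAITS = ("dbh", "height", "straightness", "volume")

#: phenotype table columns that are not traits
PHENO_KEYS = ("id", "site", "block", "family")

UNKNOWN_PARENT = "0"


class ValidationError(ValueError):
    """Raised when an input container violates its contract."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with missing mask and QC metadata.

    Parameters
    ----------
    ids
        Individual identifiers, one per row.
    markers
        Marker identifiers, one per column.
    dosages
        ``(n_samples, n_markers)`` float array of minor-allele dosages in
        ``{0, 1, 2}``; ``NaN`` marks a missing call.
    sample_qc
        Optional per-sample metadata indexed by ``ids`` with columns such as
        ``call_rate`` and ``dqc`` (chip-level dish quality control).
    marker_qc
        Optional per-marker metadata indexed by ``markers`` with columns such
        as ``call_rate``, ``fld``, ``hetso``, ``homro``.
    """

    ids: np.ndarray
    markers: np.ndarray
    dosages: np.ndarray
    sample_qc: pd.DataFrame | None = None
    marker_qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        n, m = self.dosages.shape
        if n != len(self.ids):
            raise ValidationError(
                f"dosage rows ({n}) do not match ids ({len(self.ids)})"
            )
        if m != len(self.markers):
            raise ValidationError(
                f"dosage columns ({m}) do not match markers ({len(self.markers)})"
            )
        # raw calls are 0/1/2; mean-imputed dosages are fractional but must
        # stay inside the allele-count range
        with np.errstate(invalid="ignore"):
            bad = np.logical_and(
                ~np.isnan(self.dosages),
                (self.dosages < 0.0) | (self.dosages > 2.0),
            )
        if bad.any():
            raise ValidationError("dosages must lie in [0, 2] or be NaN (missing)")

    # ---- shapes -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    # ---- derived QC ---------------------------------------------------
    def sample_call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per individual."""
        cr = 1.0 - self.missing_mask.mean(axis=1)
        return pd.Series(cr, index=self.ids, name="call_rate")

    def marker_call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per marker."""
        cr = 1.0 - self.missing_mask.mean(axis=0)
        return pd.Series(cr, index=self.markers, name="call_rate")

    # ---- subsetting ---------------------------------------------------
    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given row/column index arrays."""
        sidx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        midx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        sqc = self.sample_qc.iloc[sidx] if self.sample_qc is not None else None
        mqc = self.marker_qc.iloc[midx] if self.marker_qc is not None else None
        return GenotypeMatrix(
            ids=self.ids[sidx],
            markers=self.markers[midx],
            dosages=self.dosages[np.ix_(sidx, midx)].copy(),
            sample_qc=sqc.copy() if sqc is not None else None,
            marker_qc=mqc.copy() if mqc is not None else None,
        )

    def select_samples(self, keep_ids) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = [pos[i] for i in keep_ids]
        return self.subset(sample_idx=idx)

    def copy(self) -> "GenotypeMatrix":
        return self.subset()


@dataclass
class Pedigree:
    """Ordered individual/dam/sire triples; parents precede offspring.

    ``table`` columns: ``id, dam, sire`` (``"0"`` = unknown).  Simulated
    pedigrees additionally carry trial-placement columns (``site, block,
    family``) for progeny rows, and the generator keeps the realized pollen
    parents in ``true_sires`` for validation — those never reach the pedigree
    file a breeder would see.
    """

    table: pd.DataFrame
    true_sires: dict | None = None

    def __post_init__(self) -> None:
        for col in ("id", "dam", "sire"):
            if col not in self.table.columns:
                raise ValidationError(f"pedigree table missing column {col!r}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual ids in pedigree")
        seen: set = set()
        for _, row in self.table.iterrows():
            for parent in (row["dam"], row["sire"]):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    if parent == row["id"]:
                        raise ValidationError(f"{row['id']} is its own parent")
                    raise ValidationError(
                        f"parent {parent!r} of {row['id']!r} not listed before it"
                    )
            seen.add(row["id"])

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=object)

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["dam"] == UNKNOWN_PARENT) & (t["sire"] == UNKNOWN_PARENT)]


@dataclass
class RelationshipMatrix:
    """Symmetric additive-relationship matrix keyed by individual ids.

    ``kind`` is ``"NRM"`` (pedigree expectation) or ``"GRM"`` (marker
    realization, VanRaden method 1).
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str = "GRM"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("relationship matrix is not symmetric")
        if self.kind not in ("NRM", "GRM"):
            raise ValidationError(f"unknown relationship kind {self.kind!r}")

    def index_of(self, ids) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc

    def align(self, ids) -> np.ndarray:
        """Sub-matrix for ``ids`` in the given order."""
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def psd_repair(self, eps: float = 1e-8) -> "RelationshipMatrix":
        """Blend toward the identity when the smallest eigenvalue is < eps.

        ``G <- 0.99 G + 0.01 I`` changes entries by at most 1% while making
        the kernel numerically positive definite.  A no-op when the matrix is
        already acceptable.
        """
        if self.min_eigenvalue() >= eps:
            return self
        return RelationshipMatrix(
            ids=self.ids, values=0.99 * self.values + 0.01 * np.eye(len(self.ids)),
            kind=self.kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class VarianceComponents:
    """REML variance components for the single-kernel animal model."""

    sigma2_additive: float
    sigma2_residual: float
    standard_errors: tuple[float, float] = (np.nan, np.nan)
    covariance: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    at_lower_bound: tuple[bool, bool] = (False, False)

    @property
    def sigma2_phenotypic(self) -> float:
        return self.sigma2_additive + self.sigma2_residual


@dataclass
class FitResult:
    """Converged mixed-model fit: components, fixed effects and (G)EBVs."""

    varcomps: VarianceComponents
    fixed_estimates: pd.Series
    ebv: pd.Series
    model_kind: str  # "ABLUP" or "GBLUP"
    loglik: float = np.nan
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def heritability(self):
        from .mixedmodel import heritability_individual

        return heritability_individual(self.varcomps)


def validate_phenotypes(phenotypes: pd.DataFrame, traits=None) -> None:
    """Check the long-format phenotype contract; raise ValidationError."""
    for col in PHENO_KEYS:
        if col not in phenotypes.columns:
            raise ValidationError(f"phenotype table missing column {col!r}")
    for t in traits or ():
        if t not in phenotypes.columns:
            raise ValidationError(f"phenotype table missing trait column {t!r}")
    if phenotypes["id"].duplicated().any():
        raise ValidationError("phenotype table has duplicated individual ids")
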