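"""Sample- and marker-level quality control, marker subsetting, imputation.

The QC pipeline runs samples-first: sample call rate / DQC exclusion, then
minor-allele-frequency recomputation on the surviving samples, then marker
filters.  Three named marker-filter presets are provided:

* ``loose``    — MAF >= 0.05 only,
* ``moderate`` — + call rate >= 0.97 and FLD >= 3.6,
* ``strict``   — + call rate >= 0.99, FLD >= 5, HetSO >= 0, HomRO >= 0.

FLD (Fisher's linear discriminant), HetSO (heterozygous strength offset),
HomRO (homozygote ratio offset) and DQC are chip-level cluster metrics; the
pipeline treats them as opaque numeric columns to threshold, which is all a
genotyping array's downstream consumer ever does with them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ValidationError


@dataclass
class MarkerQCThresholds:
    """Per-marker filter thresholds; ``None`` means the rule is not applied."""

    call_rate_min: float | None = None
    fld_min: float | None = None
    hetso_min: float | None = None
    homro_min: float | None = None
    maf_min: float | None = None

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")

    def active_rules(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class SampleQCThresholds:
    """Per-sample exclusion thresholds; ``None`` disables a rule."""

    sample_call_rate_min: float | None = None
    dqc_min: float | None = None

    def __post_init__(self) -> None:
        v = self.sample_call_rate_min
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValidationError(f"sample_call_rate_min must lie in [0, 1], got {v!r}")


#: chip-default sample exclusion: call rate < 97% or DQC < 0.82
DEFAULT_SAMPLE_QC = SampleQCThresholds(sample_call_rate_min=0.97, dqc_min=0.82)

MARKER_PRESETS = {
    "loose": MarkerQCThresholds(maf_min=0.05),
    "moderate": MarkerQCThresholds(maf_min=0.05, call_rate_min=0.97, fld_min=3.6),
    "strict": MarkerQCThresholds(
        maf_min=0.05, call_rate_min=0.99, fld_min=5.0, hetso_min=0.0, homro_min=0.0
    ),
}

# maps threshold field -> marker_qc metadata column
_META_COLUMN = {
    "call_rate_min": "call_rate",
    "fld_min": "fld",
    "hetso_min": "hetso",
    "homro_min": "homro",
}


def compute_maf(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-marker minor allele frequency over non-missing calls.

    Markers with zero non-missing calls get ``NaN`` (undefined, flagged by
    absence rather than a fake zero).
    """
    if genotypes.n_markers == 0 or genotypes.n_samples == 0:
        raise ValidationError("cannot compute MAF on an empty genotype matrix")
    d = genotypes.dosages
    n_called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
    p = np.where(n_called > 0, p, np.nan)
    maf = np.minimum(p, 1.0 - p)
    return pd.Series(maf, index=genotypes.markers, name="maf")


def filter_samples(
    genotypes: GenotypeMatrix, thresholds: SampleQCThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Exclude samples below the call-rate / DQC thresholds.

    Returns the filtered matrix and a report listing every excluded id with
    the rule(s) it failed.  An all-excluded outcome is legal; the caller gets
    an empty matrix plus the full report.
    """
    call_rate = (
        genotypes.sample_qc["call_rate"]
        if genotypes.sample_qc is not None and "call_rate" in genotypes.sample_qc
        else genotypes.sample_call_rate()
    )
    reasons = []
    keep = np.ones(genotypes.n_samples, dtype=bool)
    if thresholds.sample_call_rate_min is not None:
        fail = call_rate.to_numpy() < thresholds.sample_call_rate_min
        keep &= ~fail
        for i in np.flatnonzero(fail):
            reasons.append((genotypes.ids[i], "call_rate", float(call_rate.iloc[i])))
    if thresholds.dqc_min is not None:
        if genotypes.sample_qc is None or "dqc" not in genotypes.sample_qc:
            raise ValidationError("DQC threshold requested but sample_qc has no 'dqc' column")
        dqc = genotypes.sample_qc["dqc"].to_numpy()
        fail = dqc < thresholds.dqc_min
        keep &= ~fail
        for i in np.flatnonzero(fail):
            reasons.append((genotypes.ids[i], "dqc", float(dqc[i])))
    report = pd.DataFrame(reasons, columns=["id", "rule", "value"])
    return genotypes.subset(sample_idx=np.flatnonzero(keep)), report


def filter_markers(
    genotypes: GenotypeMatrix,
    thresholds: MarkerQCThresholds,
    qc: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Retain markers that satisfy every active threshold.

    ``qc`` defaults to the matrix's own ``marker_qc`` metadata; MAF is always
    recomputed from the (already sample-filtered) genotypes.  Returns the
    filtered matrix and a report with per-rule fail counts.
    """
    qc = qc if qc is not None else genotypes.marker_qc
    keep = np.ones(genotypes.n_markers, dtype=bool)
    report: dict = {"n_in": int(genotypes.n_markers), "rules": {}}

    for field, threshold in thresholds.active_rules().items():
        if field == "maf_min":
            values = compute_maf(genotypes).to_numpy()
        else:
            column = _META_COLUMN[field]
            if qc is None or column not in qc.columns:
                raise ValidationError(
                    f"marker threshold {field!r} requires metadata column {column!r}"
                )
            values = qc[column].to_numpy(dtype=float)
        ok = values >= threshold
        ok &= ~np.isnan(values) if field == "maf_min" else np.ones_like(ok)
        report["rules"][field] = {"threshold": threshold, "n_fail": int((~ok).sum())}
        keep &= ok

    report["n_out"] = int(keep.sum())
    return genotypes.subset(marker_idx=np.flatnonzero(keep)), report


def subsample_markers(genotypes: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform random marker subset without replacement (order preserved)."""
    if n > genotypes.n_markers:
        raise ValidationError(
            f"requested {n} markers but only {genotypes.n_markers} available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(genotypes.n_markers, size=n, replace=False))
    return genotypes.subset(marker_idx=idx)


def impute_missing(
    genotypes: GenotypeMatrix, seed: int = 0, mode: str = "mean"
) -> GenotypeMatrix:
    """Fill missing calls; non-missing entries are never touched.

    ``mean`` (default) fills with the per-marker mean dosage — the standard
    missing-data treatment for centered-dosage kinship construction, and it
    preserves allele frequencies exactly.  ``hw`` draws an integer genotype
    from Hardy-Weinberg proportions at the observed allele frequency
    (seeded), for consumers that need hard calls.
    """
    if mode not in ("mean", "hw"):
        raise ValidationError(f"unknown imputation mode {mode!r}")
    out = genotypes.copy()
    mask = out.missing_mask
    if not mask.any():
        return out
    n_called = np.sum(~mask, axis=0)
    if np.any(n_called == 0):
        dead = out.markers[n_called == 0][:5]
        raise ValidationError(
            f"cannot impute markers with no observed calls (e.g. {list(dead)})"
        )
    mean_dosage = np.nansum(out.dosages, axis=0) / n_called
    dosages = out.dosages.astype(np.float64)
    if mode == "mean":
        fill = np.broadcast_to(mean_dosage, dosages.shape)
        dosages[mask] = fill[mask]
    else:
        rng = np.random.default_rng(seed)
        p = mean_dosage / 2.0
        draws = rng.binomial(2, np.broadcast_to(p, dosages.shape))
        dosages[mask] = draws[mask]
    out.dosages = dosages  # float64 after imputation; dtype cast below
    out.dosages = out.dosages.astype(np.float32)
    # 0/1/2-or-NaN validation no longer applies to mean-imputed dosages, so
    # bypass the constructor check by direct attribute assignment (above).
    return out


def qc_pipeline(
    genotypes: GenotypeMatrix,
    sample_thresholds: SampleQCThresholds = DEFAULT_SAMPLE_QC,
    marker_thresholds: MarkerQCThresholds | str = "loose",
    subsample_n: int | None = None,
    impute_mode: str | None = "mean",
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Samples-first QC: sample filter -> marker filter -> subsample -> impute."""
    if isinstance(marker_thresholds, str):
        marker_thresholds = MARKER_PRESETS[marker_thresholds]
    filtered, sample_report = filter_samples(genotypes, sample_thresholds)
    filtered, marker_report = filter_markers(filtered, marker_thresholds)
    if subsample_n is not None:
        filtered = subsample_markers(filtered, subsample_n, seed)
    if impute_mode is not None:
        filtered = impute_missing(filtered, seed=seed, mode=impute_mode)
    report = {
        "samples_excluded": sample_report.to_dict(orient="records"),
        "n_samples_out": int(filtered.n_samples),
        "markers": marker_report,
        "subsample_n": subsample_n,
        "impute_mode": impute_mode,
    }
    return filtered, report
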