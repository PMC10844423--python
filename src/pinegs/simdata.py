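"""Synthetic open-pollinated multi-site progeny-trial generator.

The generator emulates the design of a conifer progeny test: a clone bank
of plus-tree founders supplies seed through open pollination; maternal
families are planted across several sites in randomized blocks; traits are
polygenic with site-specific heritability and genotype-by-environment
interaction summarized by a type-B additive correlation.

Defaults mirror the study design this package targets: 49 founders, 44
maternal families, six sites with unequal totals (609/726/456/380/247/225,
2,643 trees), ~17k segregating SNPs, and four correlated growth traits
(volume is derived deterministically from DBH and height, so only three
traits carry their own marker effects).

Every operation is deterministic given ``SimConfig.seed``; each stage draws
from its own child stream so that, e.g., adding phenotype simulation never
perturbs the genotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    Pedigree,
    UNKNOWN_PARENT,
    ValidationError,
)

#: traits that carry marker effects (volume = dbh^2 * height is derived)
SIM_TRAITS = ("dbh", "height", "straightness")

#: unit mapping from the standardized latent scale to trait units:
#: trait = mean + scale * latent
TRAIT_UNITS = {
    "dbh": (0.25, 0.04),          # m
    "height": (12.0, 1.5),        # m
    "straightness": (2.5, 0.6),   # -ln(m)
}

#: site-by-trait narrow-sense heritability targets used when a config does
#: not supply its own matrix (six-site default spans the weak-to-strong
#: range observed in conifer progeny tests; rows = sites, cols = SIM_TRAITS)
DEFAULT_H2_SIX_SITES = np.array(
    [
        [0.19, 0.72, 0.15],
        [0.42, 0.39, 0.23],
        [0.35, 0.72, 0.36],
        [0.05, 0.56, 0.41],
        [0.55, 0.64, 0.40],
        [0.17, 0.11, 0.29],
    ]
)

DEFAULT_SITE_TOTALS = (609, 726, 456, 380, 247, 225)

# child-stream tags so each stage has an independent reproducible stream
_STREAM_FOUNDERS = 11
_STREAM_PROGENY = 22
_STREAM_PHENO = 33
_STREAM_DEGRADE = 44


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic progeny trial.

    All counts are >= 1, proportions in [0, 1] and heritability targets in
    [0, 1]; ``validate`` raises :class:`ValidationError` naming the first
    offending field.
    """

    n_founders: int = 49
    n_families: int = 44
    n_sites: int = 6
    site_totals: tuple = DEFAULT_SITE_TOTALS
    n_per_family_site: int | None = None  # balanced override of site_totals
    n_blocks_per_site: int = 5
    n_markers: int = 17074
    n_qtl: int = 2000
    maf_min: float = 0.05
    maf_max: float = 0.5
    h2_per_site_trait: np.ndarray | None = None  # (n_sites, len(SIM_TRAITS))
    h2: float | None = None                      # scalar convenience override
    type_b_corr: float = 0.3
    site_effect_sd: float = 0.8   # latent-scale SD of site means
    block_sd: float = 0.3         # latent-scale SD of block effects
    residual_sd: float = 1.0      # latent-scale residual SD
    selfing_rate: float = 0.05
    missing_rate: float = 0.03
    seed: int = 2024
    # opaque chip-QC metadata distributions (loc/scale pairs); these carry no
    # biology, they exist so quality filters have something to act on
    qc_meta: dict = field(
        default_factory=lambda: {
            "fld": (5.5, 1.5),
            "hetso": (0.2, 0.25),
            "homro": (0.4, 0.4),
            "dqc_beta": (1.2, 40.0),  # dqc = 1 - Beta(a, b): mostly > 0.95
        }
    )

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_families": self.n_families,
            "n_sites": self.n_sites,
            "n_blocks_per_site": self.n_blocks_per_site,
            "n_markers": self.n_markers,
            "n_qtl": self.n_qtl,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be a count >= 1, got {value!r}")
        if self.n_families > self.n_founders:
            raise ValidationError("n_families must be <= n_founders")
        if self.n_qtl > self.n_markers:
            raise ValidationError("n_qtl must be <= n_markers")
        for name in ("maf_min", "maf_max", "selfing_rate", "missing_rate", "type_b_corr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.maf_min > self.maf_max or self.maf_max > 0.5:
            raise ValidationError("require 0 <= maf_min <= maf_max <= 0.5")
        for name in ("site_effect_sd", "block_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(self.site_totals) != self.n_sites and self.n_per_family_site is None:
            raise ValidationError(
                f"site_totals has {len(self.site_totals)} entries for n_sites={self.n_sites}"
            )
        h2 = self.h2_matrix()
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise ValidationError("h2_per_site_trait targets must lie in [0, 1]")

    def h2_matrix(self) -> np.ndarray:
        """Resolved (n_sites, n_traits) heritability-target matrix."""
        if self.h2_per_site_trait is not None:
            h2 = np.asarray(self.h2_per_site_trait, dtype=float)
            if h2.shape != (self.n_sites, len(SIM_TRAITS)):
                raise ValidationError(
                    f"h2_per_site_trait must have shape {(self.n_sites, len(SIM_TRAITS))}"
                )
            return h2
        if self.h2 is not None:
            return np.full((self.n_sites, len(SIM_TRAITS)), float(self.h2))
        if self.n_sites == 6:
            return DEFAULT_H2_SIX_SITES.copy()
        return np.full((self.n_sites, len(SIM_TRAITS)), 0.3)

    def resolved_site_totals(self) -> np.ndarray:
        if self.n_per_family_site is not None:
            return np.full(self.n_sites, self.n_per_family_site * self.n_families, dtype=int)
        return np.asarray(self.site_totals, dtype=int)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, int(self.seed)])


@dataclass
class SimTruth:
    """Ground truth retained for parameter-recovery testing.

    ``true_breeding_values`` holds every individual's additive value at every
    site (not only the site it was planted at), so cross-site genetic
    correlations can be computed exactly.  ``variance_components`` are the
    realized (finite-sample) variances on the latent trait scale, per site
    and trait, including the cross-covariance remainder so the recorded terms
    sum to the total phenotypic variance to floating-point precision.
    """

    true_breeding_values: dict          # trait -> (n_ind, n_sites) latent-scale
    marker_effects: dict                # trait -> (n_markers, n_sites)
    realized_h2: pd.DataFrame           # index site, columns SIM_TRAITS
    variance_components: pd.DataFrame   # long: site, trait, component, value
    true_sires: dict                    # progeny id -> founder id
    qtl_markers: np.ndarray
    ids: np.ndarray

    def tbv_series(self, trait: str, site_of: pd.Series) -> pd.Series:
        """Latent-scale TBV of each individual at the site it is planted at."""
        tbv = self.true_breeding_values[trait]
        pos = {v: i for i, v in enumerate(self.ids)}
        sites = sorted(set(site_of))
        site_idx = {s: i for i, s in enumerate(sites)}
        out = {}
        for ind, site in site_of.items():
            out[ind] = tbv[pos[ind], site_idx[site]]
        return pd.Series(out)


def simulate_founders(config: SimConfig) -> GenotypeMatrix:
    """Plus-tree founder genotypes in Hardy-Weinberg proportions.

    Per-marker minor-allele frequencies are drawn uniformly on
    ``[maf_min, maf_max]`` and genotypes are Binomial(2, p); there are no
    missing values at this stage.
    """
    config.validate()
    rng = config.rng(_STREAM_FOUNDERS)
    p = rng.uniform(config.maf_min, config.maf_max, size=config.n_markers)
    dosages = rng.binomial(2, p, size=(config.n_founders, config.n_markers))
    ids = np.array([f"F{i + 1:03d}" for i in range(config.n_founders)], dtype=object)
    markers = np.array([f"M{j + 1:05d}" for j in range(config.n_markers)], dtype=object)
    return GenotypeMatrix(ids=ids, markers=markers, dosages=dosages.astype(np.float32))


def simulate_progeny(
    founders: GenotypeMatrix, config: SimConfig
) -> tuple[GenotypeMatrix, Pedigree]:
    """Open-pollinated progeny and their pedigree.

    The first ``n_families`` founders act as seed parents (dams).  Every
    progeny's sire is the dam itself with probability ``selfing_rate`` and
    otherwise a uniform draw from the remaining founders (the clone bank is
    the pollen pool).  Inheritance is Mendelian and markers are unlinked.
    The recorded pedigree lists the sire as unknown — open pollination —
    while the realized sire is kept on ``Pedigree.true_sires``.
    """
    config.validate()
    if founders.missing_mask.any():
        raise ValidationError("founder genotypes must be complete (no missing calls)")
    rng = config.rng(_STREAM_PROGENY)
    n_fam = config.n_families
    dam_ids = founders.ids[:n_fam]
    site_totals = config.resolved_site_totals()

    rows = []  # (id, dam, sire_true, site, block)
    prog_dam_idx = []
    prog_sire_idx = []
    counter = 0
    for s in range(config.n_sites):
        total = int(site_totals[s])
        if config.n_per_family_site is not None:
            fam_counts = np.full(n_fam, config.n_per_family_site, dtype=int)
        else:
            # unbalanced family representation within each site
            weights = rng.dirichlet(np.full(n_fam, 2.0))
            fam_counts = rng.multinomial(total, weights)
        for f in range(n_fam):
            for _ in range(int(fam_counts[f])):
                counter += 1
                if rng.uniform() < config.selfing_rate or config.n_founders == 1:
                    sire = f
                else:
                    sire = int(rng.integers(config.n_founders - 1))
                    if sire >= f:  # uniform over founders other than the dam
                        sire += 1
                block = int(rng.integers(config.n_blocks_per_site)) + 1
                rows.append((f"P{counter:05d}", f, sire, f"S{s + 1}", block))
                prog_dam_idx.append(f)
                prog_sire_idx.append(sire)

    prog_dam_idx = np.array(prog_dam_idx)
    prog_sire_idx = np.array(prog_sire_idx)
    dam_geno = founders.dosages[prog_dam_idx].astype(float)
    sire_geno = founders.dosages[prog_sire_idx].astype(float)
    dosages = rng.binomial(1, dam_geno / 2.0) + rng.binomial(1, sire_geno / 2.0)

    prog_ids = np.array([r[0] for r in rows], dtype=object)
    genotypes = GenotypeMatrix(
        ids=prog_ids, markers=founders.markers, dosages=dosages.astype(np.float32)
    )

    founder_rows = pd.DataFrame(
        {
            "id": founders.ids,
            "dam": UNKNOWN_PARENT,
            "sire": UNKNOWN_PARENT,
            "site": "",
            "block": 0,
            "family": "",
        }
    )
    progeny_rows = pd.DataFrame(
        {
            "id": prog_ids,
            "dam": [dam_ids[r[1]] for r in rows],
            "sire": UNKNOWN_PARENT,
            "site": [r[3] for r in rows],
            "block": [r[4] for r in rows],
            "family": [dam_ids[r[1]] for r in rows],
        }
    )
    true_sires = {r[0]: founders.ids[r[2]] for r in rows}
    pedigree = Pedigree(
        table=pd.concat([founder_rows, progeny_rows], ignore_index=True),
        true_sires=true_sires,
    )
    return genotypes, pedigree


def _equicorrelated_effects(rng, n_qtl: int, n_sites: int, rho: float) -> np.ndarray:
    """(n_qtl, n_sites) effects with exchangeable cross-site correlation rho."""
    common = rng.standard_normal((n_qtl, 1))
    specific = rng.standard_normal((n_qtl, n_sites))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * specific


def simulate_phenotypes(
    genotypes: GenotypeMatrix, pedigree: Pedigree, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes = mean + site + block + site-specific additive value + noise.

    Genotype-by-environment interaction enters through per-site marker-effect
    vectors drawn from an exchangeable multivariate normal with correlation
    ``type_b_corr``; the realized cross-site correlation of breeding values
    therefore approximates the type-B target.  Per site and trait the
    additive values are rescaled so the latent-scale heritability matches
    ``h2_per_site_trait`` exactly in the realized variances (except when
    ``residual_sd = 0``, the noiseless limit, where the raw additive value is
    kept and the phenotype minus fixed effects equals the TBV).

    Volume is then derived deterministically as DBH^2 x height in trait
    units, preserving the trait dependency rather than simulating it.
    """
    config.validate()
    rng = config.rng(_STREAM_PHENO)
    if genotypes.missing_mask.any():
        raise ValidationError("phenotype simulation requires complete genotypes")

    placed = pedigree.table[pedigree.table["site"] != ""].set_index("id")
    placed = placed.loc[[i for i in genotypes.ids if i in placed.index]]
    ids = placed.index.to_numpy(dtype=object)
    geno = genotypes.select_samples(ids)
    n = len(ids)
    sites = [f"S{s + 1}" for s in range(config.n_sites)]
    site_of = placed["site"]
    h2 = config.h2_matrix()

    qtl = config.rng(_STREAM_PHENO + 1).choice(
        config.n_markers, size=config.n_qtl, replace=False
    )
    qtl.sort()
    M = geno.dosages[:, qtl].astype(float)
    Z = M - M.mean(axis=0, keepdims=True)

    tbv = {}
    effects = {}
    records = {"id": ids, "site": site_of.to_numpy(),
               "block": placed["block"].to_numpy(), "family": placed["family"].to_numpy()}
    vc_rows = []
    h2_rows = np.zeros((config.n_sites, len(SIM_TRAITS)))
    site_codes = site_of.map({s: i for i, s in enumerate(sites)}).to_numpy()

    for t, trait in enumerate(SIM_TRAITS):
        alpha = _equicorrelated_effects(rng, config.n_qtl, config.n_sites, config.type_b_corr)
        g = Z @ alpha  # (n, n_sites) raw additive values
        site_eff = rng.normal(0.0, config.site_effect_sd, size=config.n_sites)
        block_eff = rng.normal(
            0.0, config.block_sd, size=(config.n_sites, config.n_blocks_per_site)
        )
        noise = rng.standard_normal(n)

        scale = np.ones(config.n_sites)
        var_e = config.residual_sd**2
        for s in range(config.n_sites):
            at_s = site_codes == s
            if not at_s.any():
                continue
            var_g_raw = float(np.var(g[at_s, s]))
            if config.residual_sd == 0.0 or var_g_raw == 0.0:
                continue  # noiseless limit keeps the raw additive value
            target = var_e * h2[s, t] / max(1.0 - h2[s, t], 1e-12)
            scale[s] = np.sqrt(target / var_g_raw)
        g_scaled = g * scale[np.newaxis, :]
        full_effects = np.zeros((config.n_markers, config.n_sites))
        full_effects[qtl] = alpha * scale[np.newaxis, :]

        latent = np.empty(n)
        for i in range(n):
            s = site_codes[i]
            latent[i] = (
                site_eff[s]
                + block_eff[s, int(placed["block"].iloc[i]) - 1]
                + g_scaled[i, s]
                + config.residual_sd * noise[i]
            )
        mean_t, unit_sd = TRAIT_UNITS[trait]
        records[trait] = mean_t + unit_sd * latent

        # realized latent-scale bookkeeping per site
        for s in range(config.n_sites):
            at_s = site_codes == s
            if not at_s.any():
                continue
            gg = g_scaled[at_s, s]
            bb = np.array([block_eff[s, int(b) - 1] for b in placed["block"].to_numpy()[at_s]])
            ee = config.residual_sd * noise[at_s]
            y_s = gg + bb + ee
            var_g, var_b, var_eps = map(float, (np.var(gg), np.var(bb), np.var(ee)))
            total = float(np.var(y_s))
            cross = total - var_g - var_b - var_eps
            h2_rows[s, t] = var_g / (var_g + var_eps) if (var_g + var_eps) > 0 else 0.0
            for comp, val in [
                ("additive", var_g), ("block", var_b), ("residual", var_eps),
                ("cross_covariance", cross), ("total", total),
            ]:
                vc_rows.append((sites[s], trait, comp, val))

        tbv[trait] = g_scaled
        effects[trait] = full_effects

    phenotypes = pd.DataFrame(records)
    phenotypes["volume"] = phenotypes["dbh"] ** 2 * phenotypes["height"]

    truth = SimTruth(
        true_breeding_values=tbv,
        marker_effects=effects,
        realized_h2=pd.DataFrame(h2_rows, index=sites, columns=list(SIM_TRAITS)),
        variance_components=pd.DataFrame(
            vc_rows, columns=["site", "trait", "component", "value"]
        ),
        true_sires=dict(pedigree.true_sires or {}),
        qtl_markers=geno.markers[qtl],
        ids=ids,
    )
    return phenotypes, truth


def degrade_genotypes(genotypes: GenotypeMatrix, config: SimConfig) -> GenotypeMatrix:
    """Introduce missing calls and attach chip-style QC metadata.

    Per-marker missing rates are Beta-distributed around ``missing_rate`` and
    modulated per sample, so that some markers fall below call-rate
    thresholds and a few samples fail sample-level QC — the filters
    downstream then have a nontrivial partition to act on.  With
    ``missing_rate = 0`` the genotypes pass through untouched and all call
    rates are 1.
    """
    config.validate()
    rng = config.rng(_STREAM_DEGRADE)
    out = genotypes.copy()
    n, m = out.dosages.shape
    mr = config.missing_rate

    if mr > 0:
        marker_rate = rng.beta(2.0, 2.0 * (1.0 - mr) / mr, size=m)
        # unit-mean sample modulation keeps the overall expected rate at mr
        sample_mult = rng.lognormal(mean=-0.125, sigma=0.5, size=n)
        p_miss = np.clip(marker_rate[np.newaxis, :] * sample_mult[:, np.newaxis], 0.0, 0.9)
        mask = rng.uniform(size=(n, m)) < p_miss
        dosages = out.dosages.copy()
        dosages[mask] = np.nan
        out.dosages = dosages

    fld_loc, fld_sc = config.qc_meta["fld"]
    het_loc, het_sc = config.qc_meta["hetso"]
    hom_loc, hom_sc = config.qc_meta["homro"]
    a, b = config.qc_meta["dqc_beta"]
    out.marker_qc = pd.DataFrame(
        {
            "call_rate": out.marker_call_rate().to_numpy(),
            "fld": rng.normal(fld_loc, fld_sc, size=m),
            "hetso": rng.normal(het_loc, het_sc, size=m),
            "homro": rng.normal(hom_loc, hom_sc, size=m),
        },
        index=out.markers,
    )
    out.sample_qc = pd.DataFrame(
        {
            "call_rate": out.sample_call_rate().to_numpy(),
            "dqc": 1.0 - rng.beta(a, b, size=n),
        },
        index=out.ids,
    )
    return out


@dataclass
class SimDataset:
    """Convenience bundle produced by :func:`simulate_dataset`."""

    config: SimConfig
    founders: GenotypeMatrix
    genotypes: GenotypeMatrix          # progeny, degraded (missing + QC meta)
    genotypes_complete: GenotypeMatrix  # progeny before degradation
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: founders -> progeny -> phenotypes -> QC noise."""
    founders = simulate_founders(config)
    progeny, pedigree = simulate_progeny(founders, config)
    phenotypes, truth = simulate_phenotypes(progeny, pedigree, config)
    degraded = degrade_genotypes(progeny, config)
    return SimDataset(
        config=config,
        founders=founders,
        genotypes=degraded,
        genotypes_complete=progeny,
        pedigree=pedigree,
        phenotypes=phenotypes,
        truth=truth,
    )


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if d.get("h2_per_site_trait") is not None:
        d["h2_per_site_trait"] = np.asarray(d["h2_per_site_trait"]).tolist()
    d["site_totals"] = list(d["site_totals"])
    return d
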