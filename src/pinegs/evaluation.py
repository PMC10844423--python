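"""Cross-validation scenarios and prediction-accuracy metrics.

Three training-set designs are compared:

* **within_region** — k-fold CV inside one site,
* **between_region** — train on every other site, predict one left-out
  site (the test site is additionally split into the same k subsets so a
  fold-mean directly comparable to the CV scenarios can be reported),
* **combined_region** — k-fold CV over all sites pooled, folds drawn
  regardless of region.

Two headline metrics per fold:

* **accuracy** — Pearson r between test-set GEBVs and the reference EBVs
  from a pedigree ABLUP fitted once on *all* phenotypes (the conventional
  stand-in for true breeding values in forest-tree work; it is knowingly
  circular, which is why the honest alternative below is always reported
  alongside on simulated data),
* **predictive ability** — Pearson r between test-set GEBVs and the
  fixed-effect-adjusted phenotypes, which is leakage-free.

When simulation ground truth is available a third metric, ``true
accuracy`` = r(GEBV, true breeding value), is added.  Fixed-effect
adjustment (region in multi-site scenarios, block within one site) is
estimated on training data only; a level unseen in training contributes a
constant within its fold, which Pearson correlation ignores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesalphabet import ChainConfig, canonical_model, fit_bayes, predict_gebv
from .datatypes import GenotypeMatrix, Pedigree, RelationshipMatrix, ValidationError
from .mixedmodel import ModelSpec, design_matrix, fit_reml
from .simdata import SimTruth

SCENARIOS = ("within_region", "between_region", "combined_region")
KERNEL_MODELS = ("gblup", "ablup")


@dataclass
class ScenarioSpec:
    scenario: str
    trait: str = "height"
    model: str = "gblup"
    k_folds: int = 10
    region: str | None = None
    seed: int = 0
    chain: ChainConfig | None = None  # Bayesian models only

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.scenario in ("within_region", "between_region") and self.region is None:
            raise ValidationError(f"{self.scenario} requires a region")


@dataclass
class AccuracyReport:
    scenario: str
    trait: str
    model: str
    region: str | None
    accuracy: float
    accuracy_se: float
    predictive_ability: float
    predictive_ability_se: float
    per_fold: pd.DataFrame
    true_accuracy: float = np.nan
    unsplit_accuracy: float = np.nan       # between-region only
    unsplit_predictive_ability: float = np.nan
    g_over_a: float = np.nan
    g_over_h: float = np.nan
    flags: list = field(default_factory=list)


@dataclass
class Dataset:
    """Everything the scenarios need, bundled once."""

    genotypes: GenotypeMatrix  # complete (imputed) dosages
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    grm: RelationshipMatrix
    nrm: RelationshipMatrix
    truth: SimTruth | None = None
    _reference_cache: dict = field(default_factory=dict, repr=False)

    def reference_ebv(self, trait: str) -> pd.Series:
        """Full-data pedigree ABLUP EBVs (the accuracy reference), cached."""
        if trait not in self._reference_cache:
            fixed = ["site"] if self.phenotypes["site"].nunique() > 1 else ["block"]
            fit = fit_reml(
                self.phenotypes,
                ModelSpec(response=trait, fixed_effects=fixed, random_kernel=self.nrm),
            )
            self._reference_cache[trait] = fit.ebv
        return self._reference_cache[trait]


def make_folds(ids, k: int, seed: int, stratify_by=None) -> pd.Series:
    """Random fold assignment, sizes within one of each other.

    With ``stratify_by`` (a site label per id) the round-robin deal happens
    within each stratum, starting each stratum at the currently smallest
    fold so overall sizes stay balanced too.
    """
    ids = np.asarray(ids, dtype=object)
    n = len(ids)
    if k > n:
        raise ValidationError(f"k = {k} folds exceed {n} individuals")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    # canonicalize on sorted ids so the assignment is invariant to input
    # row order (same ids + same seed => same folds)
    sort_idx = np.argsort(ids.astype(str), kind="stable")
    if stratify_by is None:
        perm = sort_idx[rng.permutation(n)]
        fold[perm] = np.arange(n) % k
    else:
        strata = np.asarray(stratify_by, dtype=object)
        counts = np.zeros(k, dtype=int)
        for s in sorted(set(strata.astype(str))):
            idx = sort_idx[strata[sort_idx].astype(str) == s]
            idx = idx[rng.permutation(len(idx))]
            order = np.argsort(counts, kind="stable")  # smallest folds first
            for j, i in enumerate(idx):
                f = int(order[j % k])
                fold[i] = f
                counts[f] += 1
    return pd.Series(fold, index=ids, name="fold")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _adjusted_phenotype(train: pd.DataFrame, test: pd.DataFrame, trait: str, fixed) -> pd.Series:
    """Remove training-estimated fixed effects from the test phenotypes."""
    X_train, names = design_matrix(train, fixed)
    y_train = train[trait].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X_train, y_train, rcond=None)
    coef = dict(zip(names, beta))

    adj = np.zeros(len(test))
    adj += coef["intercept"]
    for f in fixed:
        levels = test[f].astype(str)
        adj += np.array([coef.get(f"{f}_{lv}", 0.0) for lv in levels])
    return pd.Series(
        test[trait].to_numpy(dtype=float) - adj, index=test["id"].to_numpy(dtype=object)
    )


def _fit_and_predict(data: Dataset, train: pd.DataFrame, test_ids, trait, model, fixed, chain, seed):
    """Train `model` on `train` rows, return GEBVs for test_ids."""
    if model in KERNEL_MODELS:
        kernel = data.grm if model == "gblup" else data.nrm
        fit = fit_reml(
            train, ModelSpec(response=trait, fixed_effects=fixed, random_kernel=kernel)
        )
        return fit.ebv.loc[list(test_ids)]
    # Bayesian whole-genome regression path
    chain = chain or ChainConfig(n_iter=4000, burn_in=1000, thin=2, seed=seed)
    summary = fit_bayes(
        train, data.genotypes.select_samples(train["id"].to_numpy()), trait,
        fixed_effects=fixed, model=model, chain=chain,
    )
    test_geno = data.genotypes.select_samples(list(test_ids))
    return predict_gebv(summary, test_geno)


def run_scenario(data: Dataset, spec: ScenarioSpec) -> AccuracyReport:
    """Execute one scenario and aggregate fold-level metrics (mean +/- SE)."""
    model = spec.model if spec.model in KERNEL_MODELS else canonical_model(spec.model)
    pheno = data.phenotypes.dropna(subset=[spec.trait]).reset_index(drop=True)
    multi_site = pheno["site"].nunique() > 1
    ref_ebv = data.reference_ebv(spec.trait)
    truth = data.truth
    flags: list = []

    if spec.scenario == "within_region":
        pool = pheno[pheno["site"] == spec.region].reset_index(drop=True)
        if pool.empty:
            raise ValidationError(f"no phenotypes for region {spec.region!r}")
        fixed = ["block"]
        folds = make_folds(pool["id"].to_numpy(), spec.k_folds, spec.seed)
        splits = [
            (pool[folds.loc[pool["id"]].to_numpy() != f], pool[folds.loc[pool["id"]].to_numpy() == f])
            for f in range(spec.k_folds)
        ]
    elif spec.scenario == "combined_region":
        fixed = ["site"]
        folds = make_folds(
            pheno["id"].to_numpy(), spec.k_folds, spec.seed,
            stratify_by=pheno["site"].to_numpy(),
        )
        splits = [
            (pheno[folds.loc[pheno["id"]].to_numpy() != f], pheno[folds.loc[pheno["id"]].to_numpy() == f])
            for f in range(spec.k_folds)
        ]
    else:  # between_region
        fixed = ["site"]
        test_pool = pheno[pheno["site"] == spec.region].reset_index(drop=True)
        train_all = pheno[pheno["site"] != spec.region].reset_index(drop=True)
        if test_pool.empty or train_all.empty:
            raise ValidationError(f"region {spec.region!r} leaves an empty split")
        folds = make_folds(test_pool["id"].to_numpy(), spec.k_folds, spec.seed)
        splits = [
            (train_all, test_pool[folds.loc[test_pool["id"]].to_numpy() == f])
            for f in range(spec.k_folds)
        ]

    rows = []
    between_gebv = None
    for f, (train, test) in enumerate(splits):
        test = test.reset_index(drop=True)
        train = train.reset_index(drop=True)
        if len(test) < 3:
            flags.append(f"fold {f}: fewer than 3 test individuals, metrics undefined")
            rows.append((f, len(test), np.nan, np.nan, np.nan))
            continue
        test_ids = test["id"].to_numpy(dtype=object)
        if spec.scenario == "between_region":
            # one fit serves all subsets of the single test region
            if between_gebv is None:
                between_gebv = _fit_and_predict(
                    data, train, test_pool["id"].to_numpy(), spec.trait, model,
                    fixed, spec.chain, spec.seed,
                )
            gebv = between_gebv.loc[list(test_ids)]
        else:
            gebv = _fit_and_predict(
                data, train, test_ids, spec.trait, model, fixed, spec.chain,
                spec.seed + f,
            )
        y_adj = _adjusted_phenotype(train, test, spec.trait, fixed)
        acc = _pearson(gebv.to_numpy(), ref_ebv.loc[list(test_ids)].to_numpy())
        pa = _pearson(gebv.to_numpy(), y_adj.loc[list(test_ids)].to_numpy())
        tacc = np.nan
        if truth is not None and spec.trait in truth.true_breeding_values:
            site_of = test.set_index("id")["site"]
            tbv = truth.tbv_series(spec.trait, site_of)
            tacc = _pearson(gebv.to_numpy(), tbv.loc[list(test_ids)].to_numpy())
        rows.append((f, len(test), acc, pa, tacc))

    per_fold = pd.DataFrame(
        rows, columns=["fold", "n_test", "accuracy", "predictive_ability", "true_accuracy"]
    )

    def mean_se(col):
        vals = per_fold[col].dropna().to_numpy()
        if len(vals) == 0:
            return np.nan, np.nan
        if len(vals) == 1:
            return float(vals[0]), np.nan
        return float(np.mean(vals)), float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    acc_m, acc_se = mean_se("accuracy")
    pa_m, pa_se = mean_se("predictive_ability")
    t_m, _ = mean_se("true_accuracy")

    report = AccuracyReport(
        scenario=spec.scenario, trait=spec.trait, model=spec.model,
        region=spec.region,
        accuracy=acc_m, accuracy_se=acc_se,
        predictive_ability=pa_m, predictive_ability_se=pa_se,
        per_fold=per_fold, true_accuracy=t_m, flags=flags,
    )
    if spec.scenario == "between_region" and between_gebv is not None:
        test_ids = test_pool["id"].to_numpy(dtype=object)
        y_adj = _adjusted_phenotype(train_all, test_pool, spec.trait, fixed)
        report.unsplit_accuracy = _pearson(
            between_gebv.loc[list(test_ids)].to_numpy(),
            ref_ebv.loc[list(test_ids)].to_numpy(),
        )
        report.unsplit_predictive_ability = _pearson(
            between_gebv.loc[list(test_ids)].to_numpy(),
            y_adj.loc[list(test_ids)].to_numpy(),
        )
    return report


def standardize(
    report: AccuracyReport, ablup_report: AccuracyReport, h2: float
) -> tuple[float, float]:
    """Scale-free comparisons of genomic predictive ability.

    ``g_over_a`` divides the genomic model's predictive ability by the
    pedigree model's; it is undefined (NaN, flagged) when the pedigree
    predictive ability is not positive.  ``g_over_h`` divides by the square
    root of heritability, the theoretical ceiling of predictive ability;
    undefined when ``h2 <= 0``.
    """
    pa_g = report.predictive_ability
    pa_a = ablup_report.predictive_ability
    if pa_a is None or not np.isfinite(pa_a) or pa_a <= 0:
        g_over_a = np.nan
        report.flags.append("g_over_a undefined: ABLUP predictive ability <= 0")
    else:
        g_over_a = pa_g / pa_a
    if h2 is None or not np.isfinite(h2) or h2 <= 0:
        g_over_h = np.nan
        report.flags.append("g_over_h undefined: heritability <= 0")
    else:
        g_over_h = pa_g / np.sqrt(h2)
    report.g_over_a = g_over_a
    report.g_over_h = g_over_h
    return g_over_a, g_over_h
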