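"""Bayesian whole-genome regression (the "Bayesian alphabet").

Five marker-effect priors over the common likelihood
``y = 1 mu + Z beta + e``:

* **BRR** — one shared normal variance for all effects (ridge),
* **Bayesian LASSO (BL)** — double-exponential via the normal/exponential
  mixture of Park & Casella,
* **Bayes A** — per-marker scaled-inverse-chi-square variances,
* **Bayes B** — Bayes A plus a point mass at zero (prior exclusion
  probability ``pi``),
* **Bayes C** — shared variance plus the point mass.

Hyperpriors follow the customary heuristic: variance scales are set so the
prior mode splits the phenotypic variance according to an assumed R^2 of
0.5 between markers and residual.  Chains are single-site Gibbs samplers
(numba-compiled) and bitwise reproducible for a fixed seed.

Fixed effects other than the intercept are handled by ordinary
least-squares pre-adjustment of the response, keeping one fixed-effect
policy for the whole pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import gibbs_chain
from .datatypes import GenotypeMatrix, ValidationError

MODELS = {"BRR": 0, "BayesA": 1, "BayesB": 2, "BayesC": 3, "BL": 4}
_ALIASES = {
    "brr": "BRR", "bl": "BL", "bayesa": "BayesA", "bayesb": "BayesB",
    "bayesc": "BayesC", "bayesian_lasso": "BL", "lasso": "BL",
}


def canonical_model(name: str) -> str:
    key = name if name in MODELS else _ALIASES.get(name.lower())
    if key is None:
        raise ValidationError(f"unknown Bayesian model {name!r}; choose from {sorted(MODELS)}")
    return key


@dataclass
class ChainConfig:
    """MCMC run-length and prior hyperparameters."""

    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    df_marker: float = 5.0       # scaled-inv-chi2 df for marker variances
    df_residual: float = 5.0
    r2: float = 0.5              # assumed marker R^2 for prior scales
    pi: float = 0.99             # P(effect == 0), Bayes B/C only
    estimate_pi: bool = False    # sample pi from its Beta full conditional
    update_lambda: bool = True   # BL: sample lambda^2 under a Gamma hyperprior
    lambda_shape: float = 1.1

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValidationError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not (0.0 <= self.pi <= 1.0):
            raise ValidationError("pi must lie in [0, 1]")


@dataclass
class PosteriorSummary:
    """Posterior means and chain summaries from one Gibbs run."""

    model: str
    marker_effect_means: pd.Series
    gebv: pd.Series                  # training-set GEBVs (centered basis)
    intercept: float
    center: np.ndarray               # 2 p-hat used to center dosages
    markers: np.ndarray
    inclusion_prob: pd.Series | None
    variance_traces: dict            # name -> saved chain (post burn-in, thinned)
    effective_sample_size: dict
    n_saved: int
    chain: ChainConfig = field(repr=False, default=None)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def _adjust_response(phenotypes: pd.DataFrame, response: str, fixed_effects) -> pd.Series:
    """OLS removal of fixed-effect factor levels (training-data estimates)."""
    from .mixedmodel import design_matrix

    df = phenotypes.dropna(subset=[response]).reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    if fixed_effects:
        X, _ = design_matrix(df, list(fixed_effects))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    return pd.Series(y, index=df["id"].to_numpy(dtype=object))


def fit_bayes(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    trait: str,
    fixed_effects=(),
    model: str = "BRR",
    chain: ChainConfig | None = None,
) -> PosteriorSummary:
    """Fit one Bayesian-alphabet model for ``trait``.

    Genotypes must be complete (imputed).  Individuals are matched between
    the phenotype table and the genotype matrix by id; the response is
    pre-adjusted for the given fixed-effect factors and the sampler carries
    only an intercept.
    """
    model = canonical_model(model)
    chain = chain or ChainConfig()
    if genotypes.missing_mask.any():
        raise ValidationError("Bayesian regression requires complete genotypes")
    if chain.pi >= 1.0 and model in ("BayesB", "BayesC"):
        raise ValidationError(
            "pi = 1 excludes every marker (degenerate Bayes B/C model)"
        )

    y_adj = _adjust_response(phenotypes, trait, fixed_effects)
    if not np.all(np.isfinite(y_adj.to_numpy())):
        raise ValidationError("non-finite response values")
    geno = genotypes.select_samples(y_adj.index.to_numpy())
    M = geno.dosages.astype(np.float64)
    center = M.mean(axis=0)  # = 2 p-hat on the training set
    Z = M - center
    y = y_adj.to_numpy(dtype=float)

    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        var_y = 1e-12
    msx = float(np.sum(Z.var(axis=0)))
    msx = max(msx, 1e-12)
    frac_in = 1.0 - (chain.pi if model in ("BayesB", "BayesC") else 0.0)
    frac_in = max(frac_in, 1e-3)
    # scale chosen so the prior mode of the per-marker variance equals the
    # R^2-implied share var_y * r2 / (MSx * frac_in):
    # mode(scaled-inv-chi2(df, S)) = df S / (df + 2)
    S_b = var_y * chain.r2 / (msx * frac_in) * (chain.df_marker + 2.0) / chain.df_marker
    S_e = var_y * (1.0 - chain.r2) * (chain.df_residual + 2.0) / chain.df_residual

    # Park-Casella lambda^2 so prior-mean explained variance matches r2
    lam2_init = 2.0 * msx * (1.0 - chain.r2) / max(chain.r2, 1e-6)
    lam_shape = chain.lambda_shape if chain.update_lambda else -1.0
    lam_rate = (chain.lambda_shape - 1.0) / lam2_init if chain.update_lambda else 0.0

    beta_mean, incl_mean, mu_mean, trace_e, trace_b, trace_lam2, n_saved = gibbs_chain(
        np.ascontiguousarray(Z),
        np.ascontiguousarray(y),
        MODELS[model],
        int(chain.n_iter),
        int(chain.burn_in),
        int(chain.thin),
        int(chain.seed) % (2**31 - 1),
        float(chain.df_marker),
        float(S_b),
        float(chain.df_residual),
        float(S_e),
        float(chain.pi),
        1 if chain.estimate_pi else 0,
        float(lam2_init),
        float(lam_shape),
        float(lam_rate),
    )

    gebv = Z @ beta_mean + mu_mean
    traces = {"sigma2_e": trace_e, "sigma2_marker": trace_b}
    if model == "BL":
        traces["lambda2"] = trace_lam2
    ess = {k: _ess(v) for k, v in traces.items()}
    return PosteriorSummary(
        model=model,
        marker_effect_means=pd.Series(beta_mean, index=geno.markers),
        gebv=pd.Series(gebv, index=geno.ids),
        intercept=float(mu_mean),
        center=center,
        markers=geno.markers,
        inclusion_prob=(
            pd.Series(incl_mean, index=geno.markers)
            if model in ("BayesB", "BayesC")
            else None
        ),
        variance_traces=traces,
        effective_sample_size=ess,
        n_saved=int(n_saved),
        chain=chain,
    )


def predict_gebv(summary: PosteriorSummary, new_genotypes: GenotypeMatrix) -> pd.Series:
    """GEBV = (M - training centering) @ posterior-mean effects + intercept.

    The new matrix must contain every training marker (same coding); extra
    markers are ignored, missing ones are an error listing the absentees.
    """
    pos = {m: i for i, m in enumerate(new_genotypes.markers)}
    missing = [m for m in summary.markers if m not in pos]
    if missing:
        raise ValidationError(
            f"{len(missing)} training markers absent from prediction set, "
            f"e.g. {missing[:5]}"
        )
    idx = np.array([pos[m] for m in summary.markers], dtype=int)
    M = new_genotypes.dosages[:, idx].astype(np.float64)
    if np.isnan(M).any():
        raise ValidationError("prediction genotypes must be complete")
    Z = M - summary.center
    gebv = Z @ summary.marker_effect_means.to_numpy() + summary.intercept
    return pd.Series(gebv, index=new_genotypes.ids, name="gebv")
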