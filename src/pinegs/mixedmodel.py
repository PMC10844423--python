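"""REML variance components, BLUP breeding values, heritability, and the
type-B genetic correlation.

The workhorse is the single-kernel animal model

    y = X b + u + e,   u ~ N(0, sigma2_a K),   e ~ N(0, sigma2_e I)

with ``K`` either the pedigree NRM (ABLUP) or the marker GRM (GBLUP) and
each phenotyped individual observed once.  Estimation is EM-REML in the
eigenbasis of ``K``: after one symmetric eigendecomposition every EM
iteration costs O(n p) for p fixed-effect columns, the restricted
log-likelihood is exact, and the EM updates are provably non-decreasing in
it.  Aitken extrapolation is applied every third step and accepted only
when it improves the restricted likelihood, preserving monotonicity.

Unphenotyped individuals present in the kernel receive predictions through
the relationship structure, ``u_all = sigma2_a K[all, obs] V^{-1} (y - X b)``,
which is how cross-validation test sets are scored.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import (
    FitResult,
    RelationshipMatrix,
    ValidationError,
    VarianceComponents,
)

#: variance components are floored at this fraction of the phenotypic variance
#: (boundary estimates are reported as 0-ish values, not errors — field data
#: does produce heritabilities printed as 0.000)
VARIANCE_FLOOR_FRACTION = 1e-6


@dataclass
class ModelSpec:
    """What to fit: response, fixed-effect factors, kernel, solver knobs."""

    response: str
    fixed_effects: list
    random_kernel: RelationshipMatrix
    max_iter: int = 1000
    tol: float = 1e-8
    algorithm: str = "EM-REML"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.algorithm not in ("EM-REML",):
            raise ValidationError(f"unsupported algorithm {self.algorithm!r}")


def design_matrix(df: pd.DataFrame, factors: list) -> tuple[np.ndarray, list]:
    """Intercept + treatment-coded dummies for each factor column.

    Raises on aliased (rank-deficient) designs, naming the offending
    columns, rather than silently dropping levels.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        dummies = pd.get_dummies(df[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on the residual
        _, R, piv = _qr_pivot(X)
        aliased = [names[j] for j in piv[rank:]]
        raise ValidationError(f"singular fixed-effect design; aliased levels: {aliased}")
    return X, names


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _reml_loglik(vy, vX, d, s2a, s2e):
    """Restricted log-likelihood in the eigenbasis (vy = U'y, vX = U'X)."""
    n, p = vX.shape
    v = s2a * d + s2e
    W = vX / v[:, None]
    XtVX = vX.T @ W
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf, None, None
    beta = np.linalg.solve(XtVX, W.T @ vy)
    Py = vy / v - W @ beta
    yPy = float(vy @ Py)
    ll = -0.5 * (np.sum(np.log(v)) + logdet_x + yPy + (n - p) * np.log(2 * np.pi))
    return ll, Py, (v, W, XtVX, beta)


def fit_reml(phenotypes: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """EM-REML fit of the single-kernel animal model.

    ``phenotypes`` is the long-format table; rows with a missing response
    are dropped.  Every phenotyped id must be present in the kernel; kernel
    ids without phenotypes get genomic/pedigree predictions in the returned
    ``ebv`` series.
    """
    df = phenotypes.dropna(subset=[spec.response]).reset_index(drop=True)
    if len(df) < 2:
        raise ValidationError("need at least 2 phenotyped individuals")
    if df["id"].duplicated().any():
        raise ValidationError("one record per individual is required")
    kernel = spec.random_kernel
    obs_ids = df["id"].to_numpy(dtype=object)
    K = kernel.align(obs_ids)

    y = df[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite response values")
    X, names = design_matrix(df, spec.fixed_effects)
    n, p = X.shape

    d, U = np.linalg.eigh(K)
    if d[0] < -1e-6:
        warnings.warn(
            f"kernel has negative eigenvalue {d[0]:.3g}; clipping to zero", stacklevel=2
        )
    d = np.clip(d, 0.0, None)
    vy = U.T @ y
    vX = U.T @ X

    var_y = float(np.var(y, ddof=1))
    floor = VARIANCE_FLOOR_FRACTION * var_y
    s2a, s2e = 0.5 * var_y, 0.5 * var_y

    ll, Py, aux = _reml_loglik(vy, vX, d, s2a, s2e)
    path = [ll]
    history = [(s2a, s2e)]
    converged = False
    it = 0
    while it < spec.max_iter:
        it += 1
        v, W, XtVX, beta = aux
        # EM updates (q = n for the additive term since K is n x n)
        trPK = np.sum(d / v) - np.trace(
            np.linalg.solve(XtVX, (vX * (d / v**2)[:, None]).T @ vX)
        )
        trP = np.sum(1.0 / v) - np.trace(
            np.linalg.solve(XtVX, (vX / v[:, None] ** 2).T @ vX)
        )
        yPKPy = float(np.sum(d * Py**2))
        yPPy = float(np.sum(Py**2))
        s2a_new = max(s2a + (s2a**2 / n) * (yPKPy - trPK), floor)
        s2e_new = max(s2e + (s2e**2 / n) * (yPPy - trP), floor)

        # Aitken extrapolation on each component every third iteration
        if it % 3 == 0 and len(history) >= 2:
            acc = []
            for idx, (th2, th1, th0) in enumerate(
                zip((s2a_new, s2e_new), history[-1], history[-2])
            ):
                denom = th2 - 2 * th1 + th0
                acc.append(
                    th0 - (th1 - th0) ** 2 / denom if abs(denom) > 1e-30 else th2
                )
            acc = [max(a, floor) for a in acc]
            ll_acc, Py_acc, aux_acc = _reml_loglik(vy, vX, d, acc[0], acc[1])
            ll_em, Py_em, aux_em = _reml_loglik(vy, vX, d, s2a_new, s2e_new)
            if ll_acc > ll_em:
                s2a_new, s2e_new = acc
                ll_new, Py_new, aux_new = ll_acc, Py_acc, aux_acc
            else:
                ll_new, Py_new, aux_new = ll_em, Py_em, aux_em
        else:
            ll_new, Py_new, aux_new = _reml_loglik(vy, vX, d, s2a_new, s2e_new)

        history.append((s2a_new, s2e_new))
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        s2a, s2e, ll, Py, aux = s2a_new, s2e_new, ll_new, Py_new, aux_new
        path.append(ll)
        if rel < spec.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM-REML did not converge in {spec.max_iter} iterations", stacklevel=2
        )

    v, W, XtVX, beta = aux
    se, cov = _component_standard_errors(vX, d, v, XtVX)
    at_floor = (s2a <= floor * (1 + 1e-9), s2e <= floor * (1 + 1e-9))
    varcomps = VarianceComponents(
        sigma2_additive=float(s2a),
        sigma2_residual=float(s2e),
        standard_errors=se,
        covariance=cov,
        converged=converged,
        n_iter=it,
        at_lower_bound=at_floor,
    )

    # BLUPs: u_obs = s2a K Py;  u_all through the kernel cross-block
    Py_orig = U @ Py
    obs_idx = kernel.index_of(obs_ids)
    u_all = s2a * kernel.values[:, obs_idx] @ Py_orig
    ebv = pd.Series(u_all, index=kernel.ids, name="ebv")

    fixed = pd.Series(beta, index=names, name="estimate")
    return FitResult(
        varcomps=varcomps,
        fixed_estimates=fixed,
        ebv=ebv,
        model_kind="ABLUP" if kernel.kind == "NRM" else "GBLUP",
        loglik=float(ll),
        loglik_path=np.asarray(path),
    )


def _component_standard_errors(vX, d, v, XtVX):
    """Asymptotic SEs from the expected REML information matrix.

    I_ij = 0.5 tr(P V_i P V_j) with V_a = K (diagonal d in the eigenbasis)
    and V_e = I.  P is formed explicitly in the rotated space (n x n).
    """
    n = len(v)
    try:
        Vinv = np.diag(1.0 / v)
        W = vX / v[:, None]
        P = Vinv - W @ np.linalg.solve(XtVX, W.T)
        PK = P * d[None, :]  # P @ diag(d)
        i_aa = 0.5 * np.sum(PK * PK.T)
        i_ae = 0.5 * np.sum(PK * P.T)
        i_ee = 0.5 * np.sum(P * P.T)
        info = np.array([[i_aa, i_ae], [i_ae, i_ee]])
        cov = np.linalg.inv(info)
        se = tuple(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
        return se, cov
    except np.linalg.LinAlgError:  # pragma: no cover - singular info matrix
        return (np.nan, np.nan), None


def heritability_individual(varcomps: VarianceComponents) -> tuple[float, float]:
    """Narrow-sense h2 = sigma2_a / (sigma2_a + sigma2_e) with delta-method SE.

    Undefined (NaN, NaN) when both components sit at the lower bound.
    """
    a, e = varcomps.sigma2_additive, varcomps.sigma2_residual
    if all(varcomps.at_lower_bound):
        return (np.nan, np.nan)
    h2 = a / (a + e)
    if varcomps.covariance is None:
        return (float(h2), np.nan)
    grad = np.array([e, -a]) / (a + e) ** 2
    var_h2 = float(grad @ varcomps.covariance @ grad)
    return (float(h2), float(np.sqrt(max(var_h2, 0.0))))


def h2_significance(h2: float, se: float) -> float:
    """One-sided p-value for h2 > 0 (z-test on the REML estimate)."""
    from scipy import stats

    if not np.isfinite(se) or se == 0:
        return np.nan
    return float(stats.norm.sf(h2 / se))


# ---------------------------------------------------------------------------
# Family ANOVA (expected mean squares, method of moments)
# ---------------------------------------------------------------------------

@dataclass
class FamilyAnovaResult:
    components: dict            # raw method-of-moments estimates (can be < 0)
    components_truncated: dict  # negative estimates truncated at 0
    anova_table: pd.DataFrame
    h2_family: float
    h2_family_raw: float
    sigma_family_mean: float    # SD of family means (denominator^0.5)
    design: str


def _proj_accumulate(blocks, y):
    """Sequential (type-I) projection bookkeeping via accumulated QR.

    For the ordered design blocks, returns for each step the fitted
    sum-of-squares of ``y`` and of every random-term incidence matrix, from
    which the expected-mean-squares coefficients follow as Frobenius-norm
    differences — valid for arbitrarily unbalanced (even incomplete) cell
    structures.
    """
    from scipy.linalg import qr

    n = len(y)
    basis = np.zeros((n, 0))
    out = []
    for Xb in blocks:
        resid = Xb - basis @ (basis.T @ Xb) if basis.shape[1] else Xb.copy()
        q, r, _ = qr(resid, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = 1e-8 * max(np.linalg.norm(Xb), 1.0)
        rank = int(np.sum(diag > tol))
        basis = np.column_stack([basis, q[:, :rank]])
        out.append((basis.copy(), rank))
    return out


def _incidence(codes: pd.Series) -> np.ndarray:
    return pd.get_dummies(codes.astype(str)).to_numpy(dtype=float)


def family_anova(phenotypes: pd.DataFrame, trait: str, design: str = "single_site") -> FamilyAnovaResult:
    """Method-of-moments family variance components and family heritability.

    ``single_site`` fits  y = mu + Block + Family + Block:Family + e  and
    ``combined`` fits     y = mu + Site + Block(Site) + Family + Site:Family
    + Block:Family + e,  with blocks (and site) ordered first as the fixed
    stratum and the family terms random.  Sequential sums of squares are
    equated to their expectations; the EMS coefficients are computed
    numerically from the realized (unbalanced) cell counts, so the balanced
    textbook table is recovered as a special case.

    Family heritability uses the family-mean formula
    ``h2_f = s2_F / (s2_F + s2_SF/s + s2_BF/(s b) + s2_e/(s b nbar))`` with
    ``s`` sites (1 for single-site), ``b`` blocks and ``nbar`` the harmonic
    mean count of nonempty family-within-block cells.
    """
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    n = len(df)
    n_fam = df["family"].nunique()
    sites = sorted(df["site"].unique())
    if design == "combined" and len(sites) == 1:
        design = "single_site"  # model nesting: one site collapses to single
    if n_fam < 2:
        raise ValidationError("family ANOVA needs at least 2 families")

    if design == "single_site":
        if df["block"].nunique() < 2:
            raise ValidationError("family ANOVA needs at least 2 blocks")
        block = df["block"].astype(str)
        fam = df["family"].astype(str)
        bf = block + ":" + fam
        fixed_blocks = [np.ones((n, 1)), _incidence(block)]
        random_terms = [("family", _incidence(fam)), ("block_family", _incidence(bf))]
        n_sites_eff, n_blocks = 1, df["block"].nunique()
        cell = bf
    elif design == "combined":
        site = df["site"].astype(str)
        block = site + ":" + df["block"].astype(str)
        fam = df["family"].astype(str)
        sf = site + ":" + fam
        bf = block + ":" + fam
        if df.groupby("site")["block"].nunique().min() < 2:
            raise ValidationError("combined family ANOVA needs >= 2 blocks per site")
        fixed_blocks = [np.ones((n, 1)), _incidence(site), _incidence(block)]
        random_terms = [
            ("family", _incidence(fam)),
            ("site_family", _incidence(sf)),
            ("block_family", _incidence(bf)),
        ]
        n_sites_eff = len(sites)
        n_blocks = int(round(df.groupby("site")["block"].nunique().mean()))
        cell = bf
    else:
        raise ValidationError(f"unknown design {design!r}")

    blocks = fixed_blocks + [Z for _, Z in random_terms]
    steps = _proj_accumulate(blocks, y)
    n_fixed = len(fixed_blocks)

    # sequential SS and EMS coefficients for the random lines + error
    names = [name for name, _ in random_terms]
    Zs = [Z for _, Z in random_terms]
    ss_lines, df_lines, coefs = [], [], []
    prev_basis = steps[n_fixed - 1][0]
    for li in range(len(random_terms)):
        basis = steps[n_fixed + li][0]
        df_l = steps[n_fixed + li][1]
        fit_prev = prev_basis.T @ y
        fit_now = basis.T @ y
        ss = float(fit_now @ fit_now - fit_prev @ fit_prev)
        row = []
        for Z in Zs:
            row.append(
                float(np.sum((basis.T @ Z) ** 2) - np.sum((prev_basis.T @ Z) ** 2))
            )
        ss_lines.append(ss)
        df_lines.append(df_l)
        coefs.append(row)
        prev_basis = basis

    full_basis = steps[-1][0]
    rank_full = full_basis.shape[1]
    sse = float(y @ y - (full_basis.T @ y) @ (full_basis.T @ y))
    df_e = n - rank_full
    if df_e <= 0:
        raise ValidationError("no residual degrees of freedom for family ANOVA")

    # solve E[SS_l] = sum_c coef * s2_c + df_l * s2_e ; E[SSE] = df_e * s2_e
    k = len(names)
    Amat = np.zeros((k + 1, k + 1))
    bvec = np.zeros(k + 1)
    for li in range(k):
        Amat[li, :k] = coefs[li]
        Amat[li, k] = df_lines[li]
        bvec[li] = ss_lines[li]
    Amat[k, k] = df_e
    bvec[k] = sse
    est = np.linalg.solve(Amat, bvec)
    comp = dict(zip([*names, "residual"], est))
    comp_trunc = {kk: max(vv, 0.0) for kk, vv in comp.items()}

    counts = df.groupby(cell).size()
    nbar = len(counts) / np.sum(1.0 / counts)
    s2F = comp_trunc["family"]
    s2SF = comp_trunc.get("site_family", 0.0)
    s2BF = comp_trunc.get("block_family", 0.0)
    s2e = comp_trunc["residual"]
    denom = (
        s2F
        + s2SF / n_sites_eff
        + s2BF / (n_sites_eff * n_blocks)
        + s2e / (n_sites_eff * n_blocks * nbar)
    )
    s2F_raw = comp["family"]
    denom_raw = (
        s2F_raw
        + comp.get("site_family", 0.0) / n_sites_eff
        + comp.get("block_family", 0.0) / (n_sites_eff * n_blocks)
        + comp["residual"] / (n_sites_eff * n_blocks * nbar)
    )
    table = pd.DataFrame(
        {
            "term": [*names, "residual"],
            "df": [*df_lines, df_e],
            "ss": [*ss_lines, sse],
        }
    )
    return FamilyAnovaResult(
        components=comp,
        components_truncated=comp_trunc,
        anova_table=table,
        h2_family=float(s2F / denom) if denom > 0 else np.nan,
        h2_family_raw=float(s2F_raw / denom_raw) if denom_raw > 0 else np.nan,
        sigma_family_mean=float(np.sqrt(max(denom, 0.0))),
        design=design,
    )


# ---------------------------------------------------------------------------
# Type-B genetic correlation (bivariate two-site REML)
# ---------------------------------------------------------------------------

@dataclass
class TypeBResult:
    correlation: float
    sigma2_a: tuple
    sigma2_e: tuple
    converged: bool
    flagged: bool
    loglik: float


def type_b_correlation(
    phenotypes: pd.DataFrame,
    kernel: RelationshipMatrix,
    site_pair: tuple,
    trait: str,
    max_iter: int = 400,
) -> TypeBResult:
    """Additive correlation of one trait expressed at two sites.

    Fits the bivariate animal model with site-specific additive effects
    sharing the kernel — ``cov(u_s, u_t) = sigma_a_st K`` — plus site fixed
    effects and site-specific residual variances, by direct REML over the
    5-parameter covariance (Nelder-Mead on log-variances and atanh(r)).
    Returns ``r_B = sigma_a12 / sqrt(sigma2_a1 sigma2_a2)``; flagged NaN if
    either additive variance collapses to the boundary.
    """
    s1, s2 = site_pair
    if s1 == s2:
        return TypeBResult(1.0, (np.nan, np.nan), (np.nan, np.nan), True, False, np.nan)
    df = phenotypes[phenotypes["site"].isin([s1, s2])].dropna(subset=[trait])
    df = df.reset_index(drop=True)
    ids = df["id"].to_numpy(dtype=object)
    K = kernel.align(ids)
    y = df[trait].to_numpy(dtype=float)
    X, _ = design_matrix(df, ["site"])
    n, p = X.shape
    g1 = (df["site"] == s1).to_numpy()
    var_y = float(np.var(y, ddof=1))

    site_mask = np.where(g1, 0, 1)
    same = site_mask[:, None] == site_mask[None, :]

    def build_V(params):
        la1, la2, zr, le1, le2 = params
        sa1, sa2 = np.exp(la1), np.exp(la2)
        r = np.tanh(zr)
        sa12 = r * np.sqrt(sa1 * sa2)
        amp = np.where(same, np.where(site_mask[:, None] == 0, sa1, sa2), sa12)
        V = K * amp
        se = np.where(site_mask == 0, np.exp(le1), np.exp(le2))
        V[np.diag_indices(n)] += se
        return V, (sa1, sa2, r)

    def neg_reml(params):
        V, _ = build_V(params)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
        return 0.5 * (logdet + logdet_x + yPy + (n - p) * np.log(2 * np.pi))

    x0 = np.array(
        [np.log(0.3 * var_y)] * 2 + [np.arctanh(0.5)] + [np.log(0.6 * var_y)] * 2
    )
    res = optimize.minimize(
        neg_reml, x0, method="Nelder-Mead",
        options={"maxiter": max_iter * 5, "xatol": 1e-5, "fatol": 1e-7},
    )
    _, (sa1, sa2, r) = build_V(res.x)
    floor = VARIANCE_FLOOR_FRACTION * var_y
    flagged = sa1 <= 100 * floor or sa2 <= 100 * floor
    return TypeBResult(
        correlation=float("nan") if flagged else float(r),
        sigma2_a=(float(sa1), float(sa2)),
        sigma2_e=(float(np.exp(res.x[3])), float(np.exp(res.x[4]))),
        converged=bool(res.success),
        flagged=bool(flagged),
        loglik=float(-res.fun),
    )
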