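"""Numba Gibbs kernels for the whole-genome regression samplers.

Single-site (coordinate-wise) updates with the residual-update trick; all
randomness comes from numba's per-thread legacy NumPy RNG, seeded inside
the jitted function so a chain is bitwise reproducible for a given seed.

Model codes: 0 = BRR, 1 = BayesA, 2 = BayesB, 3 = BayesC, 4 = Bayesian
LASSO.  ``pi_excl`` is the prior probability that a marker effect is
exactly zero (Bayes B/C only); ``pi_excl = 0`` makes BayesC coincide with
BRR and BayesB with BayesA.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_inv_gauss(mu, lam):
    # Michael, Schucany & Haas (1976) transformation method
    nu = np.random.normal()
    z = nu * nu
    x = mu + (mu * mu * z) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * z + mu * mu * z * z
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.uniform(0.0, 1.0) <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.gamma(0.5 * df, 1.0)


@njit(cache=True)
def gibbs_chain(
    X,             # (n, p) centered dosages, float64
    y,             # (n,) response (fixed effects pre-adjusted)
    model,         # int code, see module docstring
    n_iter,
    burn_in,
    thin,
    seed,
    df_b,          # prior df for marker-variance scaled-inv-chi2
    S_b,           # prior scale for marker variances
    df_e,
    S_e,
    pi_excl,       # P(effect == 0) for Bayes B/C
    estimate_pi,   # 1: sample pi_excl from its Beta full conditional
    lam2_init,     # Bayesian LASSO lambda^2 starting value
    lam_shape,     # Gamma hyperprior shape for lambda^2 (<=0: keep fixed)
    lam_rate,
):
    n, p = X.shape
    np.random.seed(seed)
    xx = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s

    beta = np.zeros(p)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    resid = y - mu

    vy = 0.0
    for i in range(n):
        vy += resid[i] * resid[i]
    vy /= max(n - 1, 1)

    sigma2_e = 0.5 * vy
    sigma2_b = S_b * df_b / (df_b + 2.0)  # prior mode
    var_j = np.full(p, sigma2_b)          # per-marker variances (A/B) or tau2*s2e (BL)
    incl = np.ones(p, dtype=np.int8)
    lam2 = lam2_init
    if model == 4:
        for j in range(p):
            var_j[j] = sigma2_e * 2.0 / lam2  # tau2_j * sigma2_e with tau2 = E[tau2]

    n_save = (n_iter - burn_in + thin - 1) // thin
    beta_mean = np.zeros(p)
    incl_mean = np.zeros(p)
    mu_mean = 0.0
    trace_e = np.zeros(n_save)
    trace_b = np.zeros(n_save)
    trace_lam2 = np.zeros(n_save)
    saved = 0

    for it in range(n_iter):
        # intercept
        rsum = 0.0
        for i in range(n):
            rsum += resid[i] + mu
        mu_new = np.random.normal(rsum / n, np.sqrt(sigma2_e / n))
        delta = mu - mu_new
        for i in range(n):
            resid[i] += delta
        mu = mu_new

        # marker effects
        for j in range(p):
            b_old = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * resid[i]
            rhs += xx[j] * b_old

            if model == 2 or model == 3:
                v = var_j[j] if model == 2 else sigma2_b
                # log Bayes factor for inclusion, effect integrated out
                denom = v * xx[j] + sigma2_e
                log_bf = 0.5 * (
                    np.log(sigma2_e / denom) + v * rhs * rhs / (sigma2_e * denom)
                )
                log_odds = log_bf + np.log(1.0 - pi_excl) - np.log(
                    pi_excl if pi_excl > 0.0 else 1e-300
                )
                prob_in = 1.0 / (1.0 + np.exp(-log_odds))
                include = np.random.uniform(0.0, 1.0) < prob_in
                incl[j] = 1 if include else 0
                if not include:
                    if b_old != 0.0:
                        for i in range(n):
                            resid[i] += X[i, j] * b_old
                    beta[j] = 0.0
                    continue
                vj = v
            elif model == 0:
                vj = sigma2_b
            else:  # BayesA or BL: per-marker variance
                vj = var_j[j]

            cj = xx[j] + sigma2_e / vj
            mean_j = rhs / cj
            b_new = np.random.normal(mean_j, np.sqrt(sigma2_e / cj))
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    resid[i] += X[i, j] * diff
            beta[j] = b_new

        # variance updates
        if model == 0:
            ssb = 0.0
            for j in range(p):
                ssb += beta[j] * beta[j]
            sigma2_b = (ssb + df_b * S_b) / _chi2(df_b + p)
        elif model == 1:
            for j in range(p):
                var_j[j] = (beta[j] * beta[j] + df_b * S_b) / _chi2(df_b + 1.0)
        elif model == 2:
            for j in range(p):
                if incl[j] == 1:
                    var_j[j] = (beta[j] * beta[j] + df_b * S_b) / _chi2(df_b + 1.0)
                else:
                    var_j[j] = df_b * S_b / _chi2(df_b)  # draw from the prior
        elif model == 3:
            ssb = 0.0
            k_in = 0
            for j in range(p):
                if incl[j] == 1:
                    ssb += beta[j] * beta[j]
                    k_in += 1
            sigma2_b = (ssb + df_b * S_b) / _chi2(df_b + k_in)
        else:  # Bayesian LASSO
            sum_tau2 = 0.0
            for j in range(p):
                b2 = beta[j] * beta[j]
                if b2 < 1e-30:
                    b2 = 1e-30
                inv_tau2 = _sample_inv_gauss(np.sqrt(lam2 * sigma2_e / b2), lam2)
                tau2 = 1.0 / inv_tau2
                var_j[j] = tau2 * sigma2_e
                sum_tau2 += tau2
            if lam_shape > 0.0:
                lam2 = np.random.gamma(p + lam_shape, 1.0 / (0.5 * sum_tau2 + lam_rate))

        if (model == 2 or model == 3) and estimate_pi == 1:
            k_in = 0
            for j in range(p):
                k_in += incl[j]
            pi_excl = np.random.beta(p - k_in + 1.0, k_in + 1.0)

        sse = 0.0
        for i in range(n):
            sse += resid[i] * resid[i]
        sigma2_e = (sse + df_e * S_e) / _chi2(n + df_e)
        # (BL var_j already includes sigma2_e from the tau2 draw above)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p):
                beta_mean[j] += beta[j]
                incl_mean[j] += incl[j]
            mu_mean += mu
            vb = 0.0
            if model == 0 or model == 3:
                vb = sigma2_b
            else:
                for j in range(p):
                    vb += var_j[j]
                vb /= p
            trace_e[saved] = sigma2_e
            trace_b[saved] = vb
            trace_lam2[saved] = lam2
            saved += 1

    inv = 1.0 / max(saved, 1)
    for j in range(p):
        beta_mean[j] *= inv
        incl_mean[j] *= inv
    mu_mean *= inv
    return beta_mean, incl_mean, mu_mean, trace_e, trace_b, trace_lam2, saved
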