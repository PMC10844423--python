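"""REML estimation, BLUP, heritability, family ANOVA, type-B correlation."""
import numpy as np
import pandas as pd
import pytest

import pinegs as pg
from pinegs.datatypes import ValidationError, VarianceComponents
from pinegs.mixedmodel import (
    ModelSpec,
    family_anova,
    fit_reml,
    heritability_individual,
    type_b_correlation,
)


def _oneway_kernel(groups):
    """Block-of-ones kernel: a shared group effect as an animal-model kernel."""
    g = np.asarray(groups)
    return (g[:, None] == g[None, :]).astype(float)


def _simulate_oneway(rng, n_groups=40, per_group=10, s2a=1.0, s2e=1.0):
    groups = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0, np.sqrt(s2a), n_groups)
    y = 3.0 + u[groups] + rng.normal(0, np.sqrt(s2e), len(groups))
    df = pd.DataFrame({"id": [f"o{i}" for i in range(len(y))], "site": "S1",
                       "block": 1, "family": groups, "y": y})
    kernel = pg.RelationshipMatrix(
        ids=df["id"].to_numpy(), values=_oneway_kernel(groups), kind="GRM"
    )
    return df, kernel


class TestREML:
    def test_grid_search_oracle_single_fit(self):
        """EM-REML lands on the grid-optimum of an independently coded
        restricted likelihood (direct V construction, no eigentricks)."""
        rng = np.random.default_rng(42)
        df, kernel = _simulate_oneway(rng)
        fit = fit_reml(df, ModelSpec("y", [], kernel))
        y = df["y"].to_numpy()
        X = np.ones((len(y), 1))
        K = kernel.values

        def reml_ll(s2a, s2e):
            V = s2a * K + s2e * np.eye(len(y))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            _, ld = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtViX)
            return -0.5 * (ld + ldx + r @ Vi @ r)

        grid = np.linspace(0.4, 2.0, 33)
        lls = [(reml_ll(a, e), a, e) for a in grid for e in grid]
        _, a_best, e_best = max(lls)
        step = grid[1] - grid[0]
        assert abs(fit.varcomps.sigma2_additive - a_best) <= step
        assert abs(fit.varcomps.sigma2_residual - e_best) <= step

    def test_mean_recovery_over_replicates(self):
        est_a, est_e = [], []
        for rep in range(25):
            rng = np.random.default_rng(100 + rep)
            df, kernel = _simulate_oneway(rng)
            fit = fit_reml(df, ModelSpec("y", [], kernel))
            est_a.append(fit.varcomps.sigma2_additive)
            est_e.append(fit.varcomps.sigma2_residual)
        assert np.mean(est_a) == pytest.approx(1.0, rel=0.10)
        assert np.mean(est_e) == pytest.approx(1.0, rel=0.10)

    def test_loglik_monotone_nondecreasing(self, small_dataset):
        fit = fit_reml(
            small_dataset.phenotypes, ModelSpec("height", ["site"], small_dataset.grm)
        )
        assert np.all(np.diff(fit.loglik_path) > -1e-7)
        assert fit.varcomps.converged

    def test_noiseless_limit_recovers_phenotype(self):
        cfg = pg.SimConfig(
            n_founders=12, n_families=8, n_sites=1, site_totals=(120,),
            n_markers=300, n_qtl=300, residual_sd=0.0, missing_rate=0.0, seed=55,
        )
        sim = pg.simulate_dataset(cfg)
        grm = pg.build_grm(sim.genotypes_complete)
        fit = fit_reml(sim.phenotypes, ModelSpec("height", ["block"], grm))
        h2, _ = heritability_individual(fit.varcomps)
        assert h2 > 0.98
        ids = sim.phenotypes["id"]
        tbv = sim.truth.tbv_series("height", sim.phenotypes.set_index("id")["site"])
        r = np.corrcoef(fit.ebv.loc[ids], tbv.loc[ids])[0, 1]
        assert r > 0.99

    def test_gblup_equals_ridge_regression(self):
        """MME/REML GEBVs equal the closed-form ridge solution at matched
        lambda = c * s2e / s2a (VanRaden scaling)."""
        cfg = pg.SimConfig(
            n_founders=15, n_families=8, n_sites=1, site_totals=(50,),
            n_markers=200, n_qtl=200, h2=0.5, missing_rate=0.0, seed=11,
        )
        sim = pg.simulate_dataset(cfg)
        geno = sim.genotypes_complete
        grm = pg.build_grm(geno)
        fit = fit_reml(sim.phenotypes, ModelSpec("height", [], grm))
        M = geno.dosages.astype(float)
        p = M.mean(axis=0) / 2
        c = 2 * np.sum(p * (1 - p))
        Z = M - 2 * p
        s2a, s2e = fit.varcomps.sigma2_additive, fit.varcomps.sigma2_residual
        y = sim.phenotypes.set_index("id").loc[geno.ids, "height"].to_numpy()
        V = s2a * grm.values + s2e * np.eye(len(y))
        X = np.ones((len(y), 1))
        Vi_y, Vi_X = np.linalg.solve(V, y), np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        ystar = y - (X @ beta)
        alpha = np.linalg.solve(Z.T @ Z + (c * s2e / s2a) * np.eye(Z.shape[1]), Z.T @ ystar)
        u_ridge = Z @ alpha
        u_fit = fit.ebv.loc[geno.ids].to_numpy()
        rel = np.max(np.abs(u_fit - u_ridge)) / np.max(np.abs(u_ridge))
        assert rel < 1e-6

    def test_unphenotyped_ids_predicted_through_kernel(self, small_dataset):
        ph = small_dataset.phenotypes.iloc[:-20]
        fit = fit_reml(ph, ModelSpec("height", ["site"], small_dataset.grm))
        assert set(small_dataset.grm.ids) == set(fit.ebv.index)
        held_out = small_dataset.phenotypes.iloc[-20:]["id"]
        assert np.isfinite(fit.ebv.loc[held_out]).all()

    def test_shrinkage_bound(self, small_dataset):
        fit = fit_reml(
            small_dataset.phenotypes, ModelSpec("height", ["site"], small_dataset.grm)
        )
        bound = fit.varcomps.sigma2_additive * np.diag(small_dataset.grm.values).max()
        assert fit.ebv.var() <= bound * (1 + 1e-9)

    def test_singular_design_names_alias(self, small_dataset):
        ph = small_dataset.phenotypes.copy()
        ph["dup"] = ph["site"]  # perfectly aliased factor
        with pytest.raises(ValidationError, match="aliased"):
            fit_reml(ph, ModelSpec("height", ["site", "dup"], small_dataset.grm))

    def test_too_few_records(self, small_dataset):
        with pytest.raises(ValidationError):
            fit_reml(small_dataset.phenotypes.iloc[:1],
                     ModelSpec("height", [], small_dataset.grm))

    def test_ablup_gblup_rank_agreement(self, small_dataset):
        a = fit_reml(small_dataset.phenotypes, ModelSpec("height", ["site"], small_dataset.nrm))
        g = fit_reml(small_dataset.phenotypes, ModelSpec("height", ["site"], small_dataset.grm))
        ids = small_dataset.phenotypes["id"]
        rho = pd.Series(a.ebv.loc[ids].to_numpy()).corr(
            pd.Series(g.ebv.loc[ids].to_numpy()), method="spearman"
        )
        assert rho > 0.7

    def test_h2_ordering_across_targets(self):
        ests = {}
        for h2 in (0.2, 0.6):
            vals = []
            for rep in range(3):
                cfg = pg.SimConfig(
                    n_founders=20, n_families=12, n_sites=1, site_totals=(300,),
                    n_markers=500, n_qtl=500, h2=h2, missing_rate=0.0,
                    seed=300 + rep,
                )
                sim = pg.simulate_dataset(cfg)
                grm = pg.build_grm(sim.genotypes_complete)
                fit = fit_reml(sim.phenotypes, ModelSpec("height", ["block"], grm))
                vals.append(heritability_individual(fit.varcomps)[0])
            ests[h2] = np.mean(vals)
        assert ests[0.2] < ests[0.6]


class TestHeritability:
    @pytest.mark.parametrize(
        "a, e, expected", [(1.0, 1.0, 0.5), (0.0, 1.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_formula(self, a, e, expected):
        vc = VarianceComponents(sigma2_additive=a, sigma2_residual=e)
        h2, _ = heritability_individual(vc)
        assert h2 == pytest.approx(expected)

    def test_boundary_flagged_undefined(self):
        vc = VarianceComponents(
            sigma2_additive=1e-9, sigma2_residual=1e-9, at_lower_bound=(True, True)
        )
        h2, se = heritability_individual(vc)
        assert np.isnan(h2) and np.isnan(se)

    def test_delta_method_se_positive(self, small_dataset):
        fit = fit_reml(
            small_dataset.phenotypes, ModelSpec("height", ["site"], small_dataset.grm)
        )
        h2, se = heritability_individual(fit.varcomps)
        assert 0 < h2 < 1 and 0 < se < 1


class TestFamilyAnova:
    @staticmethod
    def _balanced(rng, b=4, f=10, n=6, s2F=2.0, s2BF=0.5, s2e=1.0):
        rows = []
        F = rng.normal(0, np.sqrt(s2F), f)
        B = rng.normal(0, 1.0, b)
        BF = rng.normal(0, np.sqrt(s2BF), (b, f))
        k = 0
        for bi in range(b):
            for fi in range(f):
                for _ in range(n):
                    y = 10 + B[bi] + F[fi] + BF[bi, fi] + rng.normal(0, np.sqrt(s2e))
                    rows.append((f"i{k}", "S1", bi + 1, f"fam{fi}", y))
                    k += 1
        return pd.DataFrame(rows, columns=["id", "site", "block", "family", "y"])

    def test_balanced_matches_textbook_ems(self):
        """On balanced data the numerical EMS solution equals the closed-form
        two-way table: s2F = (MS_F - MS_BF)/(b n), s2BF = (MS_BF - MS_E)/n."""
        rng = np.random.default_rng(7)
        df = self._balanced(rng)
        res = family_anova(df, "y", "single_site")
        b, f, n = 4, 10, 6
        cell = df.groupby(["block", "family"])["y"].mean()
        fam_mean = df.groupby("family")["y"].mean()
        blk_mean = df.groupby("block")["y"].mean()
        grand = df["y"].mean()
        ms_f = n * b * ((fam_mean - grand) ** 2).sum() / (f - 1)
        ms_bf = (
            n
            * ((cell - fam_mean.reindex(cell.index.get_level_values(1)).to_numpy()
                - blk_mean.reindex(cell.index.get_level_values(0)).to_numpy() + grand) ** 2).sum()
            / ((b - 1) * (f - 1))
        )
        sse = ((df["y"] - cell.loc[list(zip(df["block"], df["family"]))].to_numpy()) ** 2).sum()
        ms_e = sse / (b * f * (n - 1))
        assert res.components["residual"] == pytest.approx(ms_e, rel=1e-8)
        assert res.components["block_family"] == pytest.approx((ms_bf - ms_e) / n, rel=1e-6)
        assert res.components["family"] == pytest.approx((ms_f - ms_bf) / (b * n), rel=1e-6)

    def test_null_family_effect_centered_at_zero(self):
        est = []
        for rep in range(30):
            rng = np.random.default_rng(500 + rep)
            df = self._balanced(rng, b=3, f=8, n=4, s2F=0.0, s2BF=0.0, s2e=1.0)
            est.append(family_anova(df, "y", "single_site").components["family"])
        assert np.mean(est) == pytest.approx(0.0, abs=0.05)

    def test_single_site_equals_combined_with_one_site(self):
        rng = np.random.default_rng(11)
        df = self._balanced(rng)
        a = family_anova(df, "y", "single_site")
        b = family_anova(df, "y", "combined")
        for k in a.components:
            assert a.components[k] == pytest.approx(b.components[k], rel=1e-9)

    def test_degenerate_designs_error(self):
        rng = np.random.default_rng(1)
        df = self._balanced(rng, b=1, f=5, n=4)
        with pytest.raises(ValidationError):
            family_anova(df, "y", "single_site")
        df2 = self._balanced(rng, b=3, f=1, n=4)
        with pytest.raises(ValidationError):
            family_anova(df2, "y", "single_site")

    def test_unbalanced_simulated_data_runs(self, small_sim):
        res = family_anova(small_sim.phenotypes, "height", "combined")
        assert res.components["residual"] > 0
        assert np.isfinite(res.h2_family)
        assert 0 <= res.h2_family <= 1


class TestTypeB:
    def test_self_pair_is_one(self, small_dataset):
        r = type_b_correlation(
            small_dataset.phenotypes, small_dataset.grm, ("S1", "S1"), "height"
        )
        assert r.correlation == 1.0

    def test_degenerate_no_gxe(self):
        cfg = pg.SimConfig(
            n_founders=16, n_families=10, n_sites=2, site_totals=(150, 150),
            n_markers=400, n_qtl=200, h2=0.6, type_b_corr=1.0,
            missing_rate=0.0, seed=71,
        )
        sim = pg.simulate_dataset(cfg)
        grm = pg.build_grm(sim.genotypes_complete)
        res = type_b_correlation(sim.phenotypes, grm, ("S1", "S2"), "height")
        assert res.correlation > 0.9

    def test_parameter_recovery_against_simulator_truth(self):
        ests, truths = [], []
        for rep in range(8):
            cfg = pg.SimConfig(
                n_founders=30, n_families=20, n_sites=2, site_totals=(150, 150),
                n_markers=600, n_qtl=400, h2=0.5, type_b_corr=0.3,
                missing_rate=0.0, seed=800 + rep,
            )
            sim = pg.simulate_dataset(cfg)
            grm = pg.build_grm(sim.genotypes_complete)
            res = type_b_correlation(sim.phenotypes, grm, ("S1", "S2"), "height")
            ests.append(res.correlation)
            tbv = sim.truth.true_breeding_values["height"]
            truths.append(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
        assert np.mean(ests) == pytest.approx(np.mean(truths), abs=0.15)
        assert np.mean(ests) == pytest.approx(0.3, abs=0.15)
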