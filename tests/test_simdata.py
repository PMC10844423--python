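"""Generator contracts: Hardy-Weinberg founders, Mendelian progeny,
heritability targeting, variance bookkeeping, and QC degradation."""
import numpy as np
import pandas as pd
import pytest

import pinegs as pg
from pinegs.datatypes import ValidationError
from pinegs.simdata import SIM_TRAITS, degrade_genotypes


def test_invalid_config_names_field():
    with pytest.raises(ValidationError, match="n_families"):
        pg.SimConfig(n_founders=5, n_families=10).validate()
    with pytest.raises(ValidationError, match="selfing_rate"):
        pg.SimConfig(selfing_rate=1.5).validate()
    with pytest.raises(ValidationError, match="n_qtl"):
        pg.SimConfig(n_markers=10, n_qtl=20).validate()


def test_founders_hardy_weinberg_at_half():
    cfg = pg.SimConfig(
        n_founders=4000, n_families=4, n_sites=1, site_totals=(10,),
        n_markers=1, n_qtl=1, maf_min=0.5, maf_max=0.5, seed=1,
    )
    founders = pg.simulate_founders(cfg)
    counts = np.bincount(founders.dosages[:, 0].astype(int), minlength=3) / 4000
    assert counts == pytest.approx([0.25, 0.5, 0.25], abs=0.03)


def test_founders_deterministic_and_maf_bounded():
    cfg = pg.SimConfig(
        n_founders=49, n_families=44, n_sites=1, site_totals=(10,),
        n_markers=2000, n_qtl=100, maf_min=0.05, seed=5,
    )
    a = pg.simulate_founders(cfg)
    b = pg.simulate_founders(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    # brute-force allele counting oracle vs vectorized frequencies
    for j in (0, 137, 1999):
        alt = sum(int(a.dosages[i, j]) for i in range(49))
        p = alt / 98
        assert min(p, 1 - p) == pytest.approx(
            min(a.dosages[:, j].mean() / 2, 1 - a.dosages[:, j].mean() / 2), abs=1e-12
        )
    p_all = a.dosages.mean(axis=0) / 2
    maf = np.minimum(p_all, 1 - p_all)
    # binomial slack around the drawn frequency (sd <= sqrt(.5*.5/98) ~ .05)
    assert maf.min() >= 0.05 - 0.05


def test_progeny_mendelian_consistency():
    cfg = pg.SimConfig(
        n_founders=12, n_families=6, n_sites=1, site_totals=(120,),
        n_markers=150, n_qtl=50, seed=9,
    )
    founders = pg.simulate_founders(cfg)
    progeny, pedigree = pg.simulate_progeny(founders, cfg)
    fpos = {v: i for i, v in enumerate(founders.ids)}
    placed = pedigree.table[pedigree.table["site"] != ""]
    gametes = {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}
    for _, row in placed.iterrows():
        i = list(progeny.ids).index(row["id"])
        dam_g = founders.dosages[fpos[row["dam"]]]
        sire_g = founders.dosages[fpos[pedigree.true_sires[row["id"]]]]
        for j in range(progeny.n_markers):
            allowed = {a + b for a in gametes[float(dam_g[j])] for b in gametes[float(sire_g[j])]}
            assert float(progeny.dosages[i, j]) in allowed
        assert row["sire"] == "0"  # open pollination: sire unrecorded


def test_selfed_homozygous_dam_clones_itself():
    cfg = pg.SimConfig(
        n_founders=3, n_families=1, n_sites=1, site_totals=(20,),
        n_markers=50, n_qtl=10, selfing_rate=1.0, seed=2,
    )
    founders = pg.simulate_founders(cfg)
    founders.dosages[0, :] = np.where(founders.dosages[0, :] > 1, 2.0, 0.0)
    progeny, _ = pg.simulate_progeny(founders, cfg)
    assert np.array_equal(progeny.dosages, np.tile(founders.dosages[0], (20, 1)))


def test_progeny_requires_complete_founders():
    cfg = pg.SimConfig(n_founders=3, n_families=2, n_sites=1, site_totals=(5,),
                       n_markers=10, n_qtl=5, seed=3)
    founders = pg.simulate_founders(cfg)
    founders.dosages[0, 0] = np.nan
    with pytest.raises(ValidationError):
        pg.simulate_progeny(founders, cfg)


def test_half_sib_grm_matches_pedigree_expectation():
    """Within-family mean genomic relationship ~ half-sib 0.25 plus the
    full-sib excess from shared pollen parents (brute-force over true sires)."""
    cfg = pg.SimConfig(
        n_founders=30, n_families=8, n_sites=1, site_totals=(240,),
        n_markers=10000, n_qtl=100, selfing_rate=0.0, missing_rate=0.0, seed=21,
    )
    founders = pg.simulate_founders(cfg)
    progeny, pedigree = pg.simulate_progeny(founders, cfg)
    # center on founder (base-population) frequencies so coefficients are
    # comparable to pedigree expectations
    grm = pg.build_grm(progeny, freqs=founders.dosages.mean(axis=0) / 2)
    placed = pedigree.table[pedigree.table["site"] != ""].set_index("id")
    pos = {v: i for i, v in enumerate(grm.ids)}
    vals, expected = [], []
    ids = list(placed.index)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if placed.loc[ids[a], "dam"] != placed.loc[ids[b], "dam"]:
                continue
            vals.append(grm.values[pos[ids[a]], pos[ids[b]]])
            same_sire = pedigree.true_sires[ids[a]] == pedigree.true_sires[ids[b]]
            expected.append(0.5 if same_sire else 0.25)
    assert np.mean(vals) == pytest.approx(np.mean(expected), abs=0.05)


def test_dam_progeny_grm_near_half():
    cfg = pg.SimConfig(
        n_founders=25, n_families=10, n_sites=1, site_totals=(150,),
        n_markers=10000, n_qtl=100, selfing_rate=0.0, missing_rate=0.0, seed=33,
    )
    founders = pg.simulate_founders(cfg)
    progeny, pedigree = pg.simulate_progeny(founders, cfg)
    stacked = pg.GenotypeMatrix(
        ids=np.concatenate([founders.ids, progeny.ids]),
        markers=founders.markers,
        dosages=np.vstack([founders.dosages, progeny.dosages]),
    )
    grm = pg.build_grm(stacked, freqs=founders.dosages.mean(axis=0) / 2)
    pos = {v: i for i, v in enumerate(grm.ids)}
    placed = pedigree.table[pedigree.table["site"] != ""]
    pairs = [grm.values[pos[r["id"]], pos[r["dam"]]] for _, r in placed.iterrows()]
    assert np.mean(pairs) == pytest.approx(0.5, abs=0.05)


def test_noiseless_phenotype_equals_tbv():
    cfg = pg.SimConfig(
        n_founders=10, n_families=6, n_sites=1, site_totals=(80,),
        n_markers=100, n_qtl=50, residual_sd=0.0, seed=4,
    )
    sim = pg.simulate_dataset(cfg)
    from pinegs.simdata import TRAIT_UNITS

    mean_h, sd_h = TRAIT_UNITS["height"]
    latent = (sim.phenotypes["height"] - mean_h) / sd_h
    tbv = sim.truth.tbv_series("height", sim.phenotypes.set_index("id")["site"])
    fixed_part = latent.to_numpy() - tbv.loc[sim.phenotypes["id"]].to_numpy()
    # residual-free: what is left after removing the TBV is constant within block
    df = sim.phenotypes.assign(rest=fixed_part)
    assert df.groupby("block")["rest"].std().fillna(0).max() < 1e-6


def test_type_b_one_gives_identical_site_effects():
    cfg = pg.SimConfig(
        n_founders=12, n_families=8, n_sites=3, site_totals=(60, 60, 60),
        n_markers=200, n_qtl=100, type_b_corr=1.0, seed=6,
    )
    sim = pg.simulate_dataset(cfg)
    for trait in SIM_TRAITS:
        tbv = sim.truth.true_breeding_values[trait]
        # per-site scaling differs, but correlation across sites must be 1
        for s in range(1, 3):
            r = np.corrcoef(tbv[:, 0], tbv[:, s])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-10)


def test_realized_h2_near_target_montecarlo():
    """Mean realized h2 over replicates within 0.05 of the 0.4 target."""
    vals = []
    for rep in range(12):
        cfg = pg.SimConfig(
            n_founders=20, n_families=12, n_sites=1, site_totals=(500,),
            n_markers=300, n_qtl=150, h2=0.4, seed=1000 + rep,
        )
        sim = pg.simulate_dataset(cfg)
        vals.append(sim.truth.realized_h2.loc["S1", "height"])
    assert np.mean(vals) == pytest.approx(0.4, abs=0.05)


def test_variance_bookkeeping_sums_to_total(small_sim):
    vc = small_sim.truth.variance_components
    for (site, trait), grp in vc.groupby(["site", "trait"]):
        comp = grp.set_index("component")["value"]
        parts = comp[["additive", "block", "residual", "cross_covariance"]].sum()
        assert parts == pytest.approx(comp["total"], rel=1e-9, abs=1e-12)


def test_volume_is_derived_not_simulated(small_sim):
    ph = small_sim.phenotypes
    assert np.allclose(ph["volume"], ph["dbh"] ** 2 * ph["height"], rtol=1e-6)


def test_degrade_noop_at_zero_missing():
    cfg = pg.SimConfig(
        n_founders=8, n_families=4, n_sites=1, site_totals=(30,),
        n_markers=60, n_qtl=10, missing_rate=0.0, seed=8,
    )
    founders = pg.simulate_founders(cfg)
    progeny, _ = pg.simulate_progeny(founders, cfg)
    out = degrade_genotypes(progeny, cfg)
    assert np.array_equal(out.dosages, progeny.dosages)
    assert (out.marker_qc["call_rate"] == 1.0).all()
    assert (out.sample_qc["call_rate"] == 1.0).all()


def test_degrade_missing_rate_and_determinism():
    cfg = pg.SimConfig(
        n_founders=20, n_families=10, n_sites=1, site_totals=(200,),
        n_markers=10000, n_qtl=100, missing_rate=0.03, seed=12,
    )
    founders = pg.simulate_founders(cfg)
    progeny, _ = pg.simulate_progeny(founders, cfg)
    a = degrade_genotypes(progeny, cfg)
    b = degrade_genotypes(progeny, cfg)
    assert np.array_equal(a.missing_mask, b.missing_mask)
    observed = a.missing_mask.mean()
    assert observed == pytest.approx(0.03, abs=0.005)
    # brute-force count oracle agrees with the mask
    assert a.missing_mask.sum() == np.isnan(a.dosages).sum()


def test_dataset_determinism_end_to_end():
    cfg = pg.SimConfig(
        n_founders=10, n_families=6, n_sites=2, site_totals=(40, 30),
        n_markers=80, n_qtl=40, seed=77,
    )
    s1, s2 = pg.simulate_dataset(cfg), pg.simulate_dataset(cfg)
    assert np.array_equal(s1.genotypes.dosages, s2.genotypes.dosages, equal_nan=True)
    pd.testing.assert_frame_equal(s1.phenotypes, s2.phenotypes)
    pd.testing.assert_frame_equal(s1.truth.realized_h2, s2.truth.realized_h2)
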