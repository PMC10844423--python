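"""Shared fixtures: small simulated datasets reused across test modules."""
import numpy as np
import pandas as pd
import pytest

import pinegs as pg
from pinegs.markerqc import impute_missing


@pytest.fixture(scope="session")
def small_sim():
    """Two-site trial, 300 trees, 400 markers, h2 = 0.5, mild G-by-E."""
    cfg = pg.SimConfig(
        n_founders=20, n_families=12, n_sites=2, site_totals=(160, 140),
        n_markers=400, n_qtl=200, h2=0.5, type_b_corr=0.6, seed=101,
    )
    return pg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    """Evaluation-ready bundle built from ``small_sim``."""
    geno = impute_missing(small_sim.genotypes_complete)
    return pg.Dataset(
        genotypes=geno,
        pedigree=small_sim.pedigree,
        phenotypes=small_sim.phenotypes,
        grm=pg.build_grm(geno),
        nrm=pg.build_nrm(small_sim.pedigree),
        truth=small_sim.truth,
    )


@pytest.fixture
def toy_pedigree():
    """One dam, two open-pollinated progeny (sires unknown)."""
    return pg.Pedigree(
        pd.DataFrame(
            {"id": ["D", "P1", "P2"], "dam": ["0", "D", "D"], "sire": ["0", "0", "0"]}
        )
    )


def make_genotypes(dosages, ids=None, markers=None, **kw):
    d = np.asarray(dosages, dtype=np.float32)
    return pg.GenotypeMatrix(
        ids=ids or [f"i{k}" for k in range(d.shape[0])],
        markers=markers or [f"m{k}" for k in range(d.shape[1])],
        dosages=d,
        **kw,
    )
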