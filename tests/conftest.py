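"""Shared fixtures: small genotype tables and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lynxmon.popgen import GenotypeTable


def make_table(genotypes, loci=None, groups=None, destinations=None, dates=None,
               prefix="I"):
    """Build a GenotypeTable from a nested list [[(a,b), ...] per individual]."""
    geno = np.asarray(genotypes, dtype=np.int64)
    n, n_loci = geno.shape[0], geno.shape[1]
    loci = loci or [f"L{j + 1:02d}" for j in range(n_loci)]
    meta = pd.DataFrame(
        {
            "individual_id": [f"{prefix}{i:03d}" for i in range(n)],
            "sample_date": dates or ["2020-01-01"] * n,
            "group": groups or ["remnant"] * n,
            "destination": destinations or ["none"] * n,
        }
    )
    return GenotypeTable(meta, geno, loci)


@pytest.fixture
def four_individual_table():
    """One locus, genotypes (1/2),(1/1),(1/2),(2/2): Ho = 0.5 by direct count."""
    return make_table([[(1, 2)], [(1, 1)], [(1, 2)], [(2, 2)]])


@pytest.fixture(scope="session")
def drift_table_and_truth():
    """Default reinforcement history, fixed seed (shared, read-only)."""
    from lynxmon import synthdata

    cfg = synthdata.SimConfig(seed=7)
    return synthdata.simulate_drift_population(cfg.drift, cfg.rng("drift"))


@pytest.fixture(scope="session")
def scr_sim():
    """One simulated multi-session SCR dataset at the default true parameters."""
    from lynxmon import synthdata

    cfg = synthdata.SimConfig(seed=3)
    return synthdata.simulate_scr_dataset(cfg.scr, cfg.rng("scr"))
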