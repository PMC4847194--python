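import warnings

import numpy as np
import pytest

import phenolink as pl


@pytest.fixture(autouse=True)
def _quiet_rank_warnings():
    # small fixtures routinely exhaust the cross-covariance rank
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="components reduced")
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition simulated cohort, shared across tests (seed 1)."""
    cfg = pl.SimConfig(seed=1)
    table, meta, truth = pl.simulate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def within_data(default_cohort):
    """Filtered, clr-transformed, within-subject decomposed default cohort."""
    _, table, meta, truth = default_cohort
    ft = pl.filter_prevalence(table)
    clr = pl.clr_transform(ft)
    Y = meta.phenotype_matrix().to_numpy()
    diet = meta.frame["diet"].to_numpy()
    dx = pl.within_subject_split(clr.values, meta.subjects, diet)
    dy = pl.within_subject_split(Y, meta.subjects, diet)
    keep = np.array([table.otu_ids.index(o) for o in ft.otu_ids])
    return ft, meta, truth, dx, dy, keep


@pytest.fixture(scope="session")
def toy_table():
    counts = np.array([[5, 0, 1],
                       [3, 2, 0],
                       [8, 0, 0],
                       [1, 1, 0],
                       [9, 3, 0]])
    return pl.OtuTable(counts, [f"s{i}" for i in range(5)],
                       ["OTU_A", "OTU_B", "OTU_C"],
                       ["k__B;p__P1;g__a", "k__B;p__P2;g__b", "k__B;p__P1;g__c"])
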