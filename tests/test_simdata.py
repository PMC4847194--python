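import numpy as np
import pytest

import phenolink as pl
from phenolink.simdata import simulate_score_clusters


class TestSimulateCohort:
    def test_seed_determinism_byte_identical(self):
        cfg = pl.SimConfig(seed=11, n_subjects_per_arm=4, n_otus=30,
                           n_assoc_otus=5, n_age_taxa=5)
        t1, m1, tr1 = pl.simulate_cohort(cfg)
        t2, m2, tr2 = pl.simulate_cohort(cfg)
        assert np.array_equal(t1.counts, t2.counts)
        assert m1.frame.equals(m2.frame)
        assert np.array_equal(tr1.true_coefficients, tr2.true_coefficients)

    def test_null_config_zero_coefficients(self):
        cfg = pl.null_config(pl.SimConfig(seed=0, n_subjects_per_arm=3,
                                          n_otus=20, n_age_taxa=5))
        _, _, truth = pl.simulate_cohort(cfg)
        assert not truth.true_support.any()
        assert np.all(truth.true_coefficients == 0)

    def test_design_structure(self, default_cohort):
        cfg, table, meta, truth = default_cohort
        assert table.n_samples == 2 * cfg.n_subjects_per_arm * len(cfg.weeks)
        df = meta.frame
        # diet switch applies to every animal at the configured week
        assert (df.loc[df["week"] < cfg.diet_switch_week, "diet"] == "NC").all()
        assert (df.loc[df["week"] >= cfg.diet_switch_week, "diet"] == "HFD").all()
        assert set(df["treatment"]) == {"control", "STAT"}
        assert (table.counts >= 0).all()
        # truth invariants
        assert np.array_equal(truth.true_support,
                              truth.true_coefficients != 0)
        assert np.linalg.eigvalsh(truth.true_precision).min() > 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pl.SimConfig(n_otus=5, n_assoc_otus=10)
        with pytest.raises(ValueError):
            pl.SimConfig(weeks=(4, 4, 11))
        with pytest.raises(ValueError):
            pl.SimConfig(subject_sd=-1)


class TestPrecisionMatrices:
    def test_chain_hub_er_patterns(self):
        chain = pl.make_precision(6, "chain", 0.4)
        assert chain[0, 1] == -0.4 and chain[0, 2] == 0
        hub = pl.make_precision(6, "hub", 0.9)
        assert (hub[0, 1:] != 0).all()
        assert hub[1, 2] == 0
        er = pl.make_precision(30, "erdos_renyi", 0.3, seed=0, edge_prob=0.05)
        assert np.allclose(er, er.T)
        for P in (chain, hub, er):
            assert np.linalg.eigvalsh(P).min() > 0

    def test_condition_target_enforced(self):
        P = pl.make_precision(20, "chain", 0.49, condition_target=5.0)
        ev = np.linalg.eigvalsh(P)
        assert ev.max() / ev.min() <= 5.0 + 1e-6

    def test_unknown_topology(self):
        with pytest.raises(ValueError):
            pl.make_precision(5, "lattice")


class TestSimulateNetworkCounts:
    def test_fixed_seed_identical(self):
        P = pl.make_precision(10, "chain", 0.4)
        a = pl.simulate_network_counts(P, 20, seed=5)
        b = pl.simulate_network_counts(P, 20, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_asymmetric_precision_rejected(self):
        P = np.eye(4)
        P[0, 1] = 0.5
        with pytest.raises(ValueError):
            pl.simulate_network_counts(P, 10)

    def test_diagonal_precision_gives_near_empty_network(self):
        from phenolink.compositions import clr_array
        tab = pl.simulate_network_counts(np.eye(25), 300, seed=2)
        net = pl.stars_network(clr_array(tab.counts), n_subsets=15, seed=2)
        possible = 25 * 24 / 2
        assert net.n_edges <= 0.02 * possible


class TestSimulateAgeSeries:
    def test_zero_age_taxa_warns(self):
        cfg = pl.SimConfig(seed=0, n_otus=20, n_age_taxa=0, n_assoc_otus=0)
        with pytest.warns(UserWarning, match="unlearnable"):
            pl.simulate_age_series(cfg, n_samples=10)

    def test_structure_shared_noise_differs(self):
        cfg = pl.SimConfig(seed=4, n_otus=30)
        t1, a1 = pl.simulate_age_series(cfg, n_samples=20, seed=1)
        t2, _ = pl.simulate_age_series(cfg, n_samples=20, seed=2)
        assert not np.array_equal(t1.counts, t2.counts)
        t3, _ = pl.simulate_age_series(cfg, n_samples=20, seed=1)
        assert np.array_equal(t1.counts, t3.counts)


class TestScoreClusters:
    def test_shapes_and_determinism(self):
        X, lab = simulate_score_clusters(k=3, n_per=10, d=4, seed=0)
        assert X.shape == (30, 4)
        assert np.bincount(lab).tolist() == [10, 10, 10]
        X2, _ = simulate_score_clusters(k=3, n_per=10, d=4, seed=0)
        assert np.array_equal(X, X2)
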