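import numpy as np
import pytest
from scipy.stats import spearmanr

import phenolink as pl
from phenolink.simdata import simulate_disease_cohort


@pytest.fixture(scope="module")
def age_fixture():
    cfg = pl.SimConfig(seed=3)
    table, ages = pl.simulate_age_series(cfg, n_samples=150, seed=7)
    model = pl.fit_age_model(table.counts, ages, n_trees=400, seed=0)
    return cfg, table, ages, model


class TestAgeModel:
    def test_oob_predictions_track_age(self, age_fixture):
        _, _, ages, model = age_fixture
        rho = spearmanr(model.oob_prediction, ages).statistic
        assert rho >= 0.8

    def test_shuffled_ages_unlearnable(self, age_fixture):
        _, table, ages, _ = age_fixture
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(ages)
        m = pl.fit_age_model(table.counts, shuffled, n_trees=200, seed=0)
        assert abs(spearmanr(m.oob_prediction, shuffled).statistic) < 0.2

    def test_deterministic_given_seed(self, age_fixture):
        _, table, ages, model = age_fixture
        again = pl.fit_age_model(table.counts, ages, n_trees=400, seed=0)
        assert np.array_equal(model.oob_prediction, again.oob_prediction)

    def test_constant_age_is_error(self):
        with pytest.raises(ValueError):
            pl.fit_age_model(np.ones((5, 3)), [4, 4, 4, 4, 4])


@pytest.fixture(scope="module")
def maz_setup():
    cfg = pl.SimConfig(seed=3)
    weeks = np.repeat([4, 11, 16, 30], 25)
    ctrl, _ = pl.simulate_age_series(cfg, ages=weeks, seed=11)
    damp, _ = pl.simulate_age_series(cfg, ages=weeks, maturation_rate=0.4,
                                     seed=12)
    counts = np.vstack([ctrl.counts, damp.counts])
    ages = np.concatenate([weeks, weeks])
    ctrl_mask = np.concatenate([np.ones_like(weeks, bool),
                                np.zeros_like(weeks, bool)])
    model = pl.fit_age_model(ctrl.counts, weeks, n_trees=400, seed=0)
    return pl.maz_scores(model, counts, ages, ctrl_mask), ctrl_mask


class TestMazScores:
    def test_control_median_mm_zero_per_bin(self, maz_setup):
        res, ctrl_mask = maz_setup
        for b in np.unique(res.bin_id):
            sel = (res.bin_id == b) & ctrl_mask
            assert np.median(res.mm[sel]) == pytest.approx(0.0, abs=1e-12)

    def test_control_maz_sd_near_one(self, maz_setup):
        res, ctrl_mask = maz_setup
        for b in np.unique(res.bin_id):
            sel = (res.bin_id == b) & ctrl_mask
            assert res.maz[sel].std(ddof=1) == pytest.approx(1.0, abs=0.2)

    def test_delayed_arm_negative_early_maz(self, maz_setup):
        res, ctrl_mask = maz_setup
        early = (res.bin_id <= 11) & ~ctrl_mask & (res.bin_id > 4)
        assert np.mean(res.maz[early]) < 0

    def test_formula_arithmetic(self):
        # predicted 10 against bin median 8 and SD 1 -> MM = 2, MAZ = 2
        class Stub:
            oob_prediction = np.array([7.0, 8.0, 9.0])
            def predict(self, X):
                return np.array([7.0, 8.0, 9.0, 10.0])
        res = pl.maz_scores(Stub(), np.zeros((4, 2)), [5, 5, 5, 5],
                            [True, True, True, False])
        assert res.mm[3] == pytest.approx(2.0)
        assert res.maz[3] == pytest.approx(2.0)

    def test_bin_without_controls_flagged(self):
        class Stub:
            oob_prediction = np.array([4.0, 5.0])
            def predict(self, X):
                return np.array([4.0, 5.0, 9.0])
        res = pl.maz_scores(Stub(), np.zeros((3, 2)), [4, 4, 30],
                            [True, True, False])
        assert not res.valid[2]
        assert np.isnan(res.maz[2])


@pytest.fixture(scope="module")
def report():
    table, labels, weeks, marker = simulate_disease_cohort(
        weeks=(4, 16), n_otus=80, seed=5)
    rep = pl.classify_disease(table, labels, weeks, n_trees=200,
                              n_trials=1, seed=0)
    return rep, marker


class TestDiseaseClassifier:
    def test_planted_signal_beats_random_baseline(self, report):
        rep, _ = report
        assert rep.mean_error.max() < 0.25

    def test_marker_otus_dominate_importance(self, report):
        # with redundant markers and near-zero error, permuting any single
        # marker need not raise the error, so assert rank dominance: the top
        # OTU is a marker and the median marker rank sits in the top decile
        rep, marker = report
        imp = rep.importance.mean(axis=1)
        mk = [f"OTU{j:04d}" for j in marker]
        ranks = imp.rank(ascending=False)
        assert ranks.idxmin() in mk
        assert np.median(ranks[mk]) <= len(imp) / 10
        assert imp[mk].mean() > imp.drop(mk).quantile(0.9)

    def test_permuted_labels_near_baseline(self):
        table, labels, weeks, _ = simulate_disease_cohort(
            weeks=(4,), n_otus=60, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(labels)
        rep = pl.classify_disease(table, perm, weeks, n_trees=200,
                                  n_trials=1, seed=0, importance=False)
        n = (weeks == 4).sum()
        se = np.sqrt(0.25 / n)
        assert abs(rep.mean_error[4] - 0.5) < 2.5 * se + 0.1
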