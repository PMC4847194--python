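import numpy as np
import pytest

import phenolink as pl
from phenolink.spls import default_eta_grid, stars_subsample_size


def planted_regression(n=80, p=30, k_true=4, effect=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k_true] = effect * rng.choice([-1, 1], k_true)
    y = X @ beta + rng.normal(size=n)
    return X, y[:, None], beta


class TestFitSpls:
    def test_dense_pls1_first_direction_proportional_to_xty(self):
        X, y, _ = planted_regression()
        m = pl.fit_spls(X, y, eta=0.0, K=1)
        Xc = X - X.mean(0)
        yc = (y - y.mean(0)) / y.std(0, ddof=1)
        d = (Xc.T @ yc).ravel()
        w = m.W[:, 0]
        assert abs(abs(np.corrcoef(w, d)[0, 1]) - 1) < 1e-10

    def test_duplicated_column_gets_equal_weight(self):
        X, y, _ = planted_regression(seed=1)
        Xd = np.column_stack([X, X[:, 0]])
        m = pl.fit_spls(Xd, y, eta=0.3, K=2)
        assert np.allclose(m.W[0], m.W[-1], atol=1e-8)

    def test_high_eta_zeroes_noise_columns(self):
        X, y, beta = planted_regression(n=120, p=50, effect=2.0, seed=2)
        m = pl.fit_spls(X, y, eta=0.9, K=1)
        noise = beta == 0
        assert (m.W[noise, 0] == 0).mean() >= 0.9

    def test_dense_full_rank_approaches_ols(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6))
        B_true = rng.normal(size=(6, 2))
        Y = X @ B_true + 0.1 * rng.normal(size=(200, 2))
        m = pl.fit_spls(X, Y, eta=0.0, K=6, scale_y=False)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        B_ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        assert np.linalg.norm(m.B - B_ols) / np.linalg.norm(B_ols) < 1e-3

    def test_score_orthogonality_and_support_consistency(self, within_data):
        _, _, _, dx, dy, _ = within_data
        m = pl.fit_spls(dx.within, dy.within, eta=0.5, K=7)
        G = m.T.T @ m.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()
        assert set(np.nonzero(np.abs(m.B).sum(1))[0]) <= \
            set(np.nonzero(m.support)[0])

    def test_sample_permutation_invariance(self):
        X, y, _ = planted_regression(seed=3)
        m1 = pl.fit_spls(X, y, eta=0.4, K=3)
        perm = np.random.default_rng(0).permutation(len(X))
        m2 = pl.fit_spls(X[perm], y[perm], eta=0.4, K=3)
        assert np.allclose(m1.B, m2.B, atol=1e-10)

    def test_rank_exhaustion_reduces_k(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        y = X[:, :1] + 0.01 * np.random.default_rng(1).normal(size=(30, 1))
        with pytest.warns(UserWarning, match="components reduced"):
            m = pl.fit_spls(X, y, eta=0.0, K=7)
        assert m.K <= 3

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            pl.fit_spls(np.ones((4, 2)), np.ones((4, 1)), eta=1.0)


class TestStarsSelection:
    def test_xi_formula_and_brute_force_instability(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 12))
        B = np.zeros((12, 1)); B[:3] = 1.5
        y = X @ B + rng.normal(size=(60, 1))
        subjects = np.repeat(np.arange(20), 3)
        grid = np.array([0.2, 0.5, 0.8])
        prof = pl.stars_select_eta(X, y, subjects, eta_grid=grid,
                                   n_subsets=20, K=2, seed=7)
        # brute-force D from the selection frequencies
        D_brute = np.array([np.mean([2 * t * (1 - t) for t in prof.theta[:, g]])
                            for g in range(len(grid))])
        assert np.allclose(prof.D, D_brute, atol=1e-12)
        # an OTU selected in every subset contributes xi = 0;
        # theta = 0.5 contributes the maximum 0.5
        assert prof.xi.max() <= 0.5 + 1e-12
        assert np.all(prof.xi[prof.theta == 1.0] == 0)
        assert 2 * 0.5 * (1 - 0.5) == 0.5

    def test_monotone_profile_and_selection_direction(self, within_data):
        _, meta, _, dx, dy, _ = within_data
        prof = pl.stars_select_eta(dx.within, dy.within, meta.subjects, seed=0)
        rev = prof.D_monotone[::-1]
        assert np.all(np.diff(rev) >= -1e-12)  # non-decreasing toward density
        assert prof.eta_selected in prof.eta_grid
        g = np.where(prof.eta_grid == prof.eta_selected)[0][0]
        assert prof.D_monotone[g] <= prof.threshold or not prof.converged

    def test_subsample_size_convention(self):
        assert stars_subsample_size(100) == 80
        assert stars_subsample_size(400) == 200
        assert len(default_eta_grid()) == 19


class TestBootstrapSignificance:
    def test_rank_formula_minimum_p(self):
        # statistic exceeding every null draw -> p = 1/(B_null + 1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        y = (5 * X[:, :1] + 0.1 * rng.normal(size=(40, 1)))
        subjects = np.repeat(np.arange(10), 4)
        res = pl.bootstrap_significance(X, y, subjects, np.ones(4, bool),
                                        B_boot=50, B_null=2000, seed=0)
        assert res.p_values[0, 0] == pytest.approx(1 / 2001)
        assert res.p_values.min() >= 1 / 2001
        assert np.all(res.p_values <= 1.0)

    def test_planted_association_significant(self, within_data):
        ft, meta, truth, dx, dy, keep = within_data
        support = np.isin(keep, truth.assoc_otus)
        res = pl.bootstrap_significance(dx.within, dy.within, meta.subjects,
                                        support, B_boot=200, B_null=400,
                                        alpha=0.01, seed=0)
        planted = np.abs(truth.true_coefficients[keep]) > 0
        assert res.p_values[planted].min() <= 0.01
        # significant flags respect alpha
        assert np.all(res.p_values[res.significant] <= res.alpha)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            pl.bootstrap_significance(np.ones((4, 2)), np.ones((4, 1)),
                                      ["a", "a", "b", "b"], np.zeros(2, bool))
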