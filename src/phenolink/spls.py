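"""Sparse partial least squares with StARS stability selection and empirical
significance.

The model links within-subject clr features X (n x p) to within-subject
phenotype responses Y (n x q) through K latent components. Each component's
X-direction is the dominant left singular vector of the current
cross-covariance X'Y, soft-thresholded at eta times its largest absolute
entry; eta = 0 recovers dense PLS regression. Support (the selected OTU set)
is chosen by the stability approach to regularisation selection (StARS):
the model is refit over random subject-level subsets across an eta grid, the
per-OTU selection frequency theta gives the instability 2*theta*(1-theta),
and the least-sparse eta whose monotonised mean instability stays below a
variability threshold is kept. Per-association empirical p-values come from
bootstrap refits on the selected support against a subject-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class SplsModel:
    """Fitted sparse PLS regression model.

    ``B`` maps centered X to centered/scaled Y; ``support`` marks OTUs with a
    nonzero X-weight row.
    """

    eta: float
    K: int
    W: np.ndarray          # X-weights, p x K
    T: np.ndarray          # scores, n x K
    P: np.ndarray          # X-loadings, p x K
    C: np.ndarray          # response weights, q x K
    B: np.ndarray          # coefficients, p x q
    support: np.ndarray    # boolean, p
    x_mean: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.x_mean) @ self.B * self.y_scale + self.y_mean


@dataclass
class StabilityProfile:
    """StARS selection-frequency profile over an eta grid."""

    eta_grid: np.ndarray
    theta: np.ndarray        # p x n_eta selection frequencies
    D: np.ndarray            # mean instability per eta
    D_monotone: np.ndarray   # running max from the sparse end
    eta_selected: float
    threshold: float
    converged: bool          # False when no eta met the threshold
    support: np.ndarray | None = None  # full-data support at eta_selected

    @property
    def xi(self) -> np.ndarray:
        return 2.0 * self.theta * (1.0 - self.theta)


@dataclass
class AssociationResult:
    """Per (OTU, phenotype) coefficients with empirical p-values."""

    coefficients: np.ndarray   # p x q (support rows populated, others 0)
    p_values: np.ndarray       # p x q (non-support rows 1)
    significant: np.ndarray    # boolean p x q
    alpha: float
    support: np.ndarray
    n_boot: int
    n_null: int
    degenerate: np.ndarray = field(default=None)  # flagged constant coefficients


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------

def _soft_threshold(u: np.ndarray, eta: float) -> np.ndarray:
    thr = eta * np.abs(u).max()
    return np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)


def fit_spls(X: np.ndarray, Y: np.ndarray, eta: float, K: int = 7, *,
             center: bool = True, scale_y: bool = True) -> SplsModel:
    """Fit sparse PLS regression of Y on X.

    Parameters
    ----------
    eta
        Sparsity weight in [0, 1); the per-component soft threshold is
        ``eta * max|entry|`` of the dominant singular direction.
    K
        Number of latent components; reduced with a warning when it exceeds
        the rank of the cross-covariance.
    """
    if not 0 <= eta < 1:
        raise ValueError("eta must lie in [0, 1)")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]

    x_mean = X.mean(axis=0) if center else np.zeros(p)
    y_mean = Y.mean(axis=0) if center else np.zeros(q)
    Xc = X - x_mean
    Yc = Y - y_mean
    if scale_y:
        y_scale = Yc.std(axis=0, ddof=1)
        y_scale[y_scale == 0] = 1.0
    else:
        y_scale = np.ones(q)
    Yc = Yc / y_scale

    K_max = min(K, n - 1 if center else n, p, q * min(n, p))
    Ws, Ts, Ps, Cs = [], [], [], []
    Xk, Yk = Xc.copy(), Yc.copy()
    tol = 1e-12 * max(1.0, np.abs(Xc).max()) * max(1.0, np.abs(Yc).max())
    for k in range(K_max):
        M = Xk.T @ Yk
        # dominant left singular vector of the p x q cross-covariance
        if q == 1:
            s0 = np.linalg.norm(M[:, 0])
            if s0 <= tol:
                break
            u = M[:, 0] / s0
        else:
            U, S, _ = np.linalg.svd(M, full_matrices=False)
            if S[0] <= tol:
                break
            u = U[:, 0]
        w = _soft_threshold(u, eta)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p_load = Xk.T @ t / tt
        c = Yk.T @ t / tt
        Xk = Xk - np.outer(t, p_load)
        Yk = Yk - np.outer(t, c)
        Ws.append(w); Ts.append(t); Ps.append(p_load); Cs.append(c)
    k_eff = len(Ws)
    if k_eff == 0:
        W = np.zeros((p, 0)); T = np.zeros((n, 0))
        P = np.zeros((p, 0)); C = np.zeros((q, 0))
        B = np.zeros((p, q))
    else:
        if k_eff < K:
            warnings.warn(f"components reduced from {K} to {k_eff} "
                          "(cross-covariance rank exhausted)", stacklevel=2)
        W = np.column_stack(Ws); T = np.column_stack(Ts)
        P = np.column_stack(Ps); C = np.column_stack(Cs)
        # B = W (P'W)^-1 C'
        B = W @ np.linalg.solve(P.T @ W, C.T)
    support = np.abs(W).sum(axis=1) > 0
    B = np.where(support[:, None], B, 0.0)
    return SplsModel(eta, k_eff, W, T, P, C, B, support, x_mean, y_mean, y_scale)


# ---------------------------------------------------------------------------
# StARS over eta
# ---------------------------------------------------------------------------

def default_eta_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 0.951, 0.05), 2)


def stars_subsample_size(n: int) -> int:
    """StARS subset size convention: floor(10*sqrt(n)) for large n, 0.8n otherwise."""
    return int(np.floor(10 * np.sqrt(n))) if n > 144 else max(2, int(np.floor(0.8 * n)))


def stars_select_eta(Xw: np.ndarray, Yw: np.ndarray, subjects,
                     eta_grid: np.ndarray | None = None, n_subsets: int = 50,
                     subsample_fraction: float | None = None,
                     threshold: float = 0.05, K: int = 7,
                     seed: int | None = 0) -> StabilityProfile:
    """Select the sparsity weight eta by support stability over subject subsets.

    Subsets are drawn by subject — all repeated measures of a subject move
    together — so the stability estimate honours the multilevel design.
    ``eta_selected`` is the least-sparse eta whose monotonised mean
    instability D stays at or below ``threshold``; ties in D prefer the
    sparser model. The default threshold is the stability-selection
    convention beta = 0.05; pass a stricter value (e.g. 0.001) to demand
    near-perfect support stability.
    """
    Xw = np.asarray(Xw, dtype=float)
    Yw = np.asarray(Yw, dtype=float)
    subjects = np.asarray(subjects)
    if eta_grid is None:
        eta_grid = default_eta_grid()
    eta_grid = np.sort(np.asarray(eta_grid, dtype=float))
    uniq = np.unique(subjects)
    n_subj = len(uniq)
    if subsample_fraction is None:
        b = stars_subsample_size(n_subj)
    else:
        if not 0 < subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        b = max(2, int(np.floor(subsample_fraction * n_subj)))
    rng = np.random.default_rng(seed)
    p = Xw.shape[1]
    counts = np.zeros((p, len(eta_grid)), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank reductions on small subsets
        for _ in range(n_subsets):
            chosen = rng.choice(uniq, size=b, replace=False)
            mask = np.isin(subjects, chosen)
            Xs, Ys = Xw[mask], Yw[mask]
            for g, eta in enumerate(eta_grid):
                m = fit_spls(Xs, Ys, eta=eta, K=K)
                counts[:, g] += m.support
    theta = counts / n_subsets
    D = (2 * theta * (1 - theta)).mean(axis=0)
    # monotonise from the sparse (high-eta) end: running max as eta decreases
    D_rev = np.maximum.accumulate(D[::-1])[::-1]
    ok = D_rev <= threshold
    if ok.any():
        eta_selected = float(eta_grid[np.argmax(ok)])
        converged = True
    else:
        eta_selected = float(eta_grid[0])
        converged = False
        log.warning("no eta met instability threshold %g; returning densest", threshold)
    full = fit_spls(Xw, Yw, eta=eta_selected, K=K)
    return StabilityProfile(eta_grid, theta, D, D_rev, eta_selected,
                            threshold, converged, support=full.support)


# ---------------------------------------------------------------------------
# Bootstrap / permutation significance
# ---------------------------------------------------------------------------

def _subject_blocks(subjects: np.ndarray) -> dict:
    blocks: dict = {}
    for i, s in enumerate(subjects):
        blocks.setdefault(s, []).append(i)
    return {s: np.asarray(ix) for s, ix in blocks.items()}


def bootstrap_significance(Xw: np.ndarray, Yw: np.ndarray, subjects,
                           support: np.ndarray, B_boot: int = 2000,
                           B_null: int | None = None, alpha: float = 0.01,
                           K: int = 7, seed: int | None = 0,
                           p_statistic: str = "original") -> AssociationResult:
    """Empirical p-values for each (OTU, phenotype) coefficient on a fixed support.

    Bootstrap: subjects resampled with replacement, dense PLS refit on the
    support; the reported coefficient is the median over refits. Null: the
    subject-to-response assignment is randomly permuted and the model refit;
    the two-sided p-value is ``(1 + #{|null| >= |observed|}) / (1 + B_null)``,
    so p is never zero. ``p_statistic`` chooses the observed statistic the
    null is compared against: the original-fit coefficient (default; exactly
    calibrated under the null) or the bootstrap "median".
    """
    Xw = np.asarray(Xw, dtype=float)
    Yw = np.asarray(Yw, dtype=float)
    subjects = np.asarray(subjects)
    support = np.asarray(support, dtype=bool)
    if B_null is None:
        B_null = B_boot
    q = Yw.shape[1] if Yw.ndim > 1 else 1
    p = Xw.shape[1]
    idx = np.where(support)[0]
    if idx.size == 0:
        raise ValueError("empty support; nothing to test")
    Xr = Xw[:, idx]
    rng = np.random.default_rng(seed)
    blocks = _subject_blocks(subjects)
    subj_list = list(blocks)
    sizes = {len(ix) for ix in blocks.values()}
    balanced = len(sizes) == 1
    if not balanced:
        log.warning("unbalanced subject blocks; null permutes rows, not blocks")
    Kr = min(K, len(idx), q if q > 1 else 1, Xr.shape[0] - 1)
    Kr = max(Kr, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = fit_spls(Xr, Yw, eta=0.0, K=Kr).B  # |support| x q
        boots = np.empty((B_boot, len(idx), q))
        for b in range(B_boot):
            chosen = rng.choice(subj_list, size=len(subj_list), replace=True)
            rows = np.concatenate([blocks[s] for s in chosen])
            boots[b] = fit_spls(Xr[rows], Yw[rows], eta=0.0, K=Kr).B
        nulls = np.empty((B_null, len(idx), q))
        for b in range(B_null):
            if balanced:
                perm = rng.permutation(len(subj_list))
                rows = np.concatenate(
                    [blocks[subj_list[perm[i]]] for i in range(len(subj_list))])
            else:
                rows = rng.permutation(Xr.shape[0])
            nulls[b] = fit_spls(Xr, Yw[rows], eta=0.0, K=Kr).B

    if p_statistic not in ("original", "median"):
        raise ValueError("p_statistic must be 'original' or 'median'")
    coef_r = np.median(boots, axis=0)
    stat = obs if p_statistic == "original" else coef_r
    degen = boots.std(axis=0) == 0
    p_r = (1.0 + (np.abs(nulls) >= np.abs(stat)[None]).sum(axis=0)) / (1.0 + B_null)

    coefficients = np.zeros((p, q))
    p_values = np.ones((p, q))
    degenerate = np.zeros((p, q), dtype=bool)
    coefficients[idx] = coef_r
    p_values[idx] = p_r
    degenerate[idx] = degen
    significant = p_values <= alpha
    return AssociationResult(coefficients, p_values, significant, alpha,
                             support, B_boot, B_null, degenerate)
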