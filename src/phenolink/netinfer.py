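"""Microbial association networks by neighborhood selection with StARS.

Each OTU's clr abundance is regressed on all others with an L1 penalty
(node-wise lasso, the Meinshausen–Bühlmann estimator of the sparse inverse
covariance). An edge joins two OTUs when either regression keeps the other
(OR symmetrisation); its sign is that of the larger-magnitude coefficient.
The penalty is chosen by StARS: graphs are refit over random sample subsets
along a decreasing lambda path, and the densest graph whose monotonised mean
edge instability 2*theta*(1-theta) stays below a variability threshold wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .spls import stars_subsample_size

log = logging.getLogger(__name__)


@dataclass
class AssociationNetwork:
    """Signed undirected OTU graph with StARS selection frequencies."""

    graph: nx.Graph
    otu_ids: list[str]
    lambda_selected: float | None = None
    instability: np.ndarray | None = None       # D per lambda on the grid
    lambda_grid: np.ndarray | None = None
    converged: bool = True
    phylum: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def lambda_max(X: np.ndarray) -> float:
    """Largest useful penalty: max absolute off-diagonal empirical correlation."""
    Xs = _standardize(X)
    n = Xs.shape[0]
    C = Xs.T @ Xs / (n - 1)
    np.fill_diagonal(C, 0.0)
    return float(np.abs(C).max())


def default_lambda_grid(X: np.ndarray, n_lambda: int = 30,
                        ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to lambda_max*ratio."""
    lmax = lambda_max(X)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _neighborhood_path(X: np.ndarray, lambdas: np.ndarray,
                       standardize: bool = True) -> np.ndarray:
    """Node-wise lasso coefficients for every lambda at once.

    Returns array (L, p, p): entry [l, j, i] is the coefficient of predictor
    i in the regression of node j at lambdas[l]. Lambda matches the
    1/(2n)*RSS + lambda*||b||_1 objective used by scikit-learn.
    """
    Xs = _standardize(X) if standardize else np.asarray(X, dtype=float)
    n, p = Xs.shape
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(lambdas)[::-1]  # lasso_path wants decreasing alphas
    coefs = np.zeros((len(lambdas), p, p))
    others = np.arange(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            pred = others[others != j]
            _, cj, _ = lasso_path(Xs[:, pred], Xs[:, j], alphas=lambdas[order],
                                  max_iter=3000, tol=1e-5)
            # cj: (len(pred), L) in decreasing-alpha order
            for li, l_orig in enumerate(order):
                coefs[l_orig, j, pred] = cj[:, li]
    return coefs


def _merge_adjacency(coefs_l: np.ndarray, merge: str = "or") -> np.ndarray:
    """Symmetrise node-wise coefficients into a signed weighted adjacency."""
    A = coefs_l
    Bt = A.T
    nz_a, nz_b = A != 0, Bt != 0
    if merge == "or":
        edge = nz_a | nz_b
    elif merge == "and":
        edge = nz_a & nz_b
    else:
        raise ValueError("merge must be 'or' or 'and'")
    pick_a = np.abs(A) >= np.abs(Bt)
    w = np.where(pick_a, A, Bt) * edge
    w = np.where(np.abs(w) >= np.abs(w.T), w, w.T)  # enforce symmetry
    np.fill_diagonal(w, 0.0)
    return w


def mb_neighborhood(X_clr: np.ndarray, lam: float, *, standardize: bool = True,
                    merge: str = "or") -> np.ndarray:
    """Signed adjacency from node-wise lasso at a single penalty."""
    if lam <= 0:
        n, p = np.asarray(X_clr).shape
        if p > n:
            raise ValueError("lambda = 0 with p > n is unidentifiable")
        raise ValueError("lambda must be positive")
    coefs = _neighborhood_path(X_clr, np.array([lam]), standardize=standardize)
    return _merge_adjacency(coefs[0], merge=merge)


def stars_network(X_clr: np.ndarray, otu_ids=None, lambda_grid=None,
                  n_subsets: int = 50, threshold: float = 0.05,
                  seed: int | None = 0, merge: str = "or",
                  phylum: dict | None = None) -> AssociationNetwork:
    """Infer an association network with StARS-selected penalty.

    ``threshold`` is the instability bound, defaulting to the stability
    selection convention beta = 0.05; a literal percentage reading (0.0005)
    is available through the same argument. Subsets are rows (samples)
    without replacement of size ``stars_subsample_size(n)``.
    """
    X_clr = np.asarray(X_clr, dtype=float)
    n, p = X_clr.shape
    if otu_ids is None:
        otu_ids = [f"otu{i}" for i in range(p)]
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X_clr)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    b = stars_subsample_size(n)
    rng = np.random.default_rng(seed)
    L = len(lambda_grid)
    edge_counts = np.zeros((L, p, p))
    for _ in range(n_subsets):
        rows = rng.choice(n, size=b, replace=False)
        coefs = _neighborhood_path(X_clr[rows], lambda_grid)
        for l in range(L):
            edge_counts[l] += _merge_adjacency(coefs[l], merge=merge) != 0
    theta = edge_counts / n_subsets
    iu = np.triu_indices(p, k=1)
    xi = 2 * theta * (1 - theta)
    D = np.array([xi[l][iu].mean() for l in range(L)])
    D_bar = np.maximum.accumulate(D)  # monotone toward denser graphs
    ok = D_bar <= threshold
    if ok.any():
        sel = np.where(ok)[0][-1]  # largest index still under threshold = densest stable
        converged = True
    else:
        sel = 0  # sparsest graph
        converged = False
        log.warning("no lambda met instability threshold %g; returning sparsest",
                    threshold)
    lam = float(lambda_grid[sel])
    W = mb_neighborhood(X_clr, lam, merge=merge)
    g = nx.Graph()
    phylum = phylum or {}
    for i, oid in enumerate(otu_ids):
        g.add_node(oid, phylum=phylum.get(oid, "unknown"))
    for i, j in zip(*np.nonzero(np.triu(W, k=1))):
        g.add_edge(otu_ids[i], otu_ids[j], weight=abs(W[i, j]),
                   sign=int(np.sign(W[i, j])),
                   stars_frequency=float(theta[sel, i, j]))
    return AssociationNetwork(g, list(otu_ids), lam, D, lambda_grid,
                              converged, phylum)
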