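"""Graphlet-based network comparison, robustness simulation, and topology summaries.

Networks are compared through per-node graphlet orbit signatures: exact
counts of the 15 automorphism orbits of connected graphlets on up to four
nodes (orbit 0 is plain degree). The Spearman correlation matrix over the 11
non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11} is a size-independent network
summary, and the Frobenius norm between two such matrices is the graphlet
correlation distance (GCD). Robustness to node removal is scored with natural
connectivity, ln of the mean exponential of adjacency eigenvalues.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.linalg import eigvalsh
from scipy.special import logsumexp
from scipy.stats import spearmanr, rankdata

#: Orbits kept for graphlet correlation (the non-redundant subset).
NONREDUNDANT_ORBITS = (0, 1, 2, 4, 5, 6, 7, 8, 9, 10, 11)
N_ORBITS = 15


@dataclass
class OrbitSignature:
    """Per-node counts of the 15 graphlet orbits on <=4-node graphlets."""

    counts: np.ndarray  # n_nodes x 15, non-negative integers
    nodes: list

    @property
    def nonredundant(self) -> np.ndarray:
        return self.counts[:, list(NONREDUNDANT_ORBITS)]


@dataclass
class AttackCurve:
    """Natural connectivity as nodes are sequentially removed."""

    strategy: str
    fraction_removed: np.ndarray
    connectivity: np.ndarray
    n_rep: int = 1
    seed: int | None = None


# ---------------------------------------------------------------------------
# Orbit counting
# ---------------------------------------------------------------------------

def _check_simple(graph: nx.Graph) -> None:
    if graph.is_multigraph() or graph.is_directed():
        raise ValueError("simple undirected graph required")
    if any(u == v for u, v in graph.edges()):
        raise ValueError("self-loops are not allowed")


def _connected_subsets(adj: list[set], k: int):
    """Wernicke's ESU: yield each connected k-node subset exactly once."""
    n = len(adj)

    def extend(sub: set, ext: set, v: int):
        if len(sub) == k:
            yield frozenset(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            excl = {u for u in adj[w]
                    if u > v and u not in sub and all(u not in adj[s] for s in sub)}
            yield from extend(sub | {w}, ext | excl, v)

    for v in range(n):
        yield from extend({v}, {u for u in adj[v] if u > v}, v)


def count_orbits(graph: nx.Graph) -> OrbitSignature:
    """Exact per-node orbit counts over induced connected subgraphs of size <=4."""
    _check_simple(graph)
    nodes = sorted(graph.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    adj = [set(index[v] for v in graph.neighbors(u)) for u in nodes]
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    counts[:, 0] = [len(a) for a in adj]

    for sub in _connected_subsets(adj, 3):
        a, b, c = sorted(sub)
        deg = {u: sum(1 for v in sub if v != u and v in adj[u]) for u in sub}
        m = sum(deg.values()) // 2
        if m == 3:  # triangle
            for u in sub:
                counts[u, 3] += 1
        else:  # path P3
            for u in sub:
                counts[u, 2 if deg[u] == 2 else 1] += 1

    for sub in _connected_subsets(adj, 4):
        deg = {u: sum(1 for v in sub if v != u and v in adj[u]) for u in sub}
        m = sum(deg.values()) // 2
        seq = sorted(deg.values())
        if m == 3:
            if seq == [1, 1, 1, 3]:  # claw
                for u in sub:
                    counts[u, 7 if deg[u] == 3 else 6] += 1
            else:  # path P4: [1, 1, 2, 2]
                for u in sub:
                    counts[u, 5 if deg[u] == 2 else 4] += 1
        elif m == 4:
            if seq == [2, 2, 2, 2]:  # 4-cycle
                for u in sub:
                    counts[u, 8] += 1
            else:  # tailed triangle: [1, 2, 2, 3]
                for u in sub:
                    counts[u, 9 if deg[u] == 1 else (11 if deg[u] == 3 else 10)] += 1
        elif m == 5:  # diamond (K4 minus an edge)
            for u in sub:
                counts[u, 13 if deg[u] == 3 else 12] += 1
        else:  # m == 6, complete K4
            for u in sub:
                counts[u, 14] += 1
    return OrbitSignature(counts, nodes)


def _poly2(A: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(A))] + [A[:, i] for i in range(A.shape[1])]
    for i in range(A.shape[1]):
        for j in range(i, A.shape[1]):
            cols.append(A[:, i] * A[:, j])
    return np.column_stack(cols)


def verify_nonredundant_orbits(seed: int = 0, n_graphs: int = 60,
                               tol: float = 1e-6) -> dict:
    """Check that the 11-orbit subset is exactly the non-redundant one.

    Over an ensemble of random graphs, each excluded orbit (3, 12, 13, 14)
    must be an exact polynomial function of the other fourteen orbit counts
    (the excluded set eliminates jointly: e.g. the complete-graphlet orbit is
    determined only once the triangle and diamond orbits are available),
    while no retained orbit is so expressible from the other ten retained —
    i.e. the non-redundant set has exactly 11 members. Returns residuals.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(4, 9):
        for _ in range(n_graphs):
            g = nx.gnp_random_graph(n, rng.uniform(0.15, 0.85),
                                    seed=int(rng.integers(2 ** 31 - 1)))
            rows.append(count_orbits(g).counts)
    M = np.vstack(rows).astype(float)
    keep = list(NONREDUNDANT_ORBITS)

    def max_resid(target_col, basis_cols):
        F = _poly2(M[:, basis_cols])
        coef, *_ = np.linalg.lstsq(F, M[:, target_col], rcond=None)
        return float(np.abs(F @ coef - M[:, target_col]).max())

    redundant = {o: max_resid(o, [k for k in range(N_ORBITS) if k != o])
                 for o in range(N_ORBITS) if o not in keep}
    retained = {o: max_resid(o, [k for k in keep if k != o]) for o in keep}
    ok = (all(r <= tol for r in redundant.values())
          and all(r > tol for r in retained.values()))
    return {"redundant_residuals": redundant, "retained_residuals": retained,
            "nonredundant_count": len(keep) if ok else None}


def graphlet_correlation_matrix(sig: OrbitSignature) -> np.ndarray:
    """11x11 Spearman correlation matrix across nodes of the non-redundant orbits.

    A single all-ones dummy row is appended before correlating so that orbits
    constant across all nodes (typically all-zero) still have a defined rank
    correlation.
    """
    X = sig.nonredundant.astype(float)
    if X.shape[0] < 1:
        raise ValueError("at least one node required")
    X = np.vstack([X, np.ones(X.shape[1])])
    with np.errstate(invalid="ignore"):
        rho = spearmanr(X, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    # columns still constant after the dummy row: co-constant orbit pairs are
    # perfectly correlated by convention, constant-vs-varying pairs are 0
    const = X.std(axis=0) == 0
    for i, j in zip(*np.nonzero(np.isnan(rho))):
        rho[i, j] = 1.0 if const[i] and const[j] else 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def gcd(gcm_a: np.ndarray, gcm_b: np.ndarray) -> float:
    """Graphlet correlation distance: Frobenius norm of the upper-triangle difference."""
    gcm_a = np.asarray(gcm_a, dtype=float)
    gcm_b = np.asarray(gcm_b, dtype=float)
    if gcm_a.shape != gcm_b.shape:
        raise ValueError("correlation matrices must share a shape")
    iu = np.triu_indices(gcm_a.shape[0], k=1)
    return float(np.linalg.norm(gcm_a[iu] - gcm_b[iu]))


def graphlet_correlation_distance(graph_a: nx.Graph, graph_b: nx.Graph) -> float:
    """GCD straight from two graphs."""
    return gcd(graphlet_correlation_matrix(count_orbits(graph_a)),
               graphlet_correlation_matrix(count_orbits(graph_b)))


# ---------------------------------------------------------------------------
# Embedding and spectra
# ---------------------------------------------------------------------------

def embed_networks(distance_matrix: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Coordinates are centered; orientation is fixed by requiring the first
    row's coordinates to be non-negative.
    """
    D = np.asarray(distance_matrix, dtype=float)
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dim]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for d in range(coords.shape[1]):
        if coords[0, d] < 0:
            coords[:, d] *= -1
    return coords


def natural_connectivity(graph: nx.Graph) -> float:
    """ln of the average exponential of adjacency eigenvalues (Estrada-type index).

    Zero for an edgeless graph; strictly increases when an edge is added.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined on the empty node set")
    if graph.number_of_edges() == 0:
        return 0.0
    A = nx.to_numpy_array(graph, weight=None)
    lam = eigvalsh(A)
    return float(logsumexp(lam) - np.log(n))


# ---------------------------------------------------------------------------
# Attacks
# ---------------------------------------------------------------------------

def _removal_order(g: nx.Graph, strategy: str, rng, adaptive: bool) -> list:
    g = g.copy()
    order = []
    if strategy == "random":
        nodes = sorted(g.nodes())
        rng.shuffle(nodes)
        return nodes
    score = {"degree": lambda h: dict(h.degree()),
             "betweenness": nx.betweenness_centrality}[strategy]
    if not adaptive:
        s = score(g)
        return sorted(g.nodes(), key=lambda u: (-s[u], str(u)))
    while g.number_of_nodes() > 1:
        s = score(g)
        u = min(g.nodes(), key=lambda u: (-s[u], str(u)))
        order.append(u)
        g.remove_node(u)
    order.extend(g.nodes())
    return order


def attack_curve(graph: nx.Graph, strategy: str, n_rep: int = 50,
                 seed: int | None = 0, adaptive: bool = True) -> AttackCurve:
    """Natural connectivity under sequential node removal.

    ``strategy`` is one of random / degree / betweenness. Targeted rankings
    are recomputed after every removal by default (adaptive mode); the random
    strategy averages ``n_rep`` independent removal orders.
    """
    if strategy not in ("random", "degree", "betweenness"):
        raise ValueError(f"unknown strategy {strategy!r}")
    N = graph.number_of_nodes()
    if N == 0:
        raise ValueError("empty graph")
    fracs = np.arange(N) / N
    reps = n_rep if strategy == "random" else 1
    rng = np.random.default_rng(seed)
    curves = np.zeros((reps, N))
    for r in range(reps):
        g = graph.copy()
        order = _removal_order(graph, strategy, rng, adaptive)
        curves[r, 0] = natural_connectivity(g)
        for k, u in enumerate(order[:N - 1], start=1):
            g.remove_node(u)
            curves[r, k] = natural_connectivity(g)
    return AttackCurve(strategy, fracs, curves.mean(axis=0), reps, seed)


# ---------------------------------------------------------------------------
# Summaries and keystones
# ---------------------------------------------------------------------------

def _as_graph(net) -> nx.Graph:
    return net.graph if hasattr(net, "graph") and isinstance(net.graph, nx.Graph) else net


def summary_stats(net) -> dict:
    """Global topology summary: sizes, diameter, centralities, modularity, assortativity."""
    g = _as_graph(net)
    out = {"n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
    if g.number_of_nodes() == 0:
        return out
    comps = list(nx.connected_components(g))
    giant = g.subgraph(max(comps, key=len))
    out["diameter"] = nx.diameter(giant) if giant.number_of_nodes() > 1 else 0
    out["mean_degree"] = 2 * g.number_of_edges() / g.number_of_nodes()
    out["mean_betweenness"] = float(np.mean(list(
        nx.betweenness_centrality(g).values())))
    if g.number_of_edges() > 0:
        comms = nx.community.greedy_modularity_communities(g)
        out["modularity"] = nx.community.modularity(g, comms)
        phyla = nx.get_node_attributes(g, "phylum")
        if phyla and len(set(phyla.values())) > 1:
            out["phylum_assortativity"] = nx.attribute_assortativity_coefficient(
                g, "phylum")
    return out


def top_keystones(net, k: int = 2) -> list[dict]:
    """Rank nodes as keystones: joint hub (degree) and bottleneck (betweenness).

    Score = degree rank + betweenness rank (rank 1 = largest value); ties are
    broken by higher betweenness, then lexical node id.
    """
    g = _as_graph(net)
    nodes = sorted(g.nodes(), key=str)
    if not nodes:
        return []
    deg = np.array([g.degree(u) for u in nodes], dtype=float)
    bet_d = nx.betweenness_centrality(g)
    bet = np.array([bet_d[u] for u in nodes])
    r_deg = rankdata(-deg, method="average")
    r_bet = rankdata(-bet, method="average")
    score = r_deg + r_bet
    order = sorted(range(len(nodes)), key=lambda i: (score[i], -bet[i], str(nodes[i])))
    return [{"otu": nodes[i], "degree": int(deg[i]), "betweenness": float(bet[i]),
             "rank_score": float(score[i])} for i in order[:k]]
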