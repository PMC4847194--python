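import itertools

import numpy as np
import networkx as nx
import pytest

import phenolink as pl
from phenolink.nettopo import NONREDUNDANT_ORBITS


def brute_force_orbits(g):
    """Independent oracle: classify every <=4-node induced subgraph directly."""
    nodes = sorted(g.nodes())
    idx = {u: i for i, u in enumerate(nodes)}
    cnt = np.zeros((len(nodes), 15), dtype=int)
    for u in nodes:
        cnt[idx[u], 0] = g.degree(u)
    for size in (3, 4):
        for sub in itertools.combinations(nodes, size):
            h = g.subgraph(sub)
            if not nx.is_connected(h):
                continue
            deg = dict(h.degree())
            m = h.number_of_edges()
            seq = sorted(deg.values())
            for u in sub:
                d = deg[u]
                if size == 3:
                    o = 3 if m == 3 else (2 if d == 2 else 1)
                elif m == 3:
                    o = ((7 if d == 3 else 6) if seq == [1, 1, 1, 3]
                         else (5 if d == 2 else 4))
                elif m == 4:
                    o = (8 if seq == [2, 2, 2, 2]
                         else (9 if d == 1 else (11 if d == 3 else 10)))
                elif m == 5:
                    o = 13 if d == 3 else 12
                else:
                    o = 14
                cnt[idx[u], o] += 1
    return cnt


class TestOrbitCounting:
    def test_triangle_smallest_case(self):
        sig = pl.count_orbits(nx.complete_graph(3))
        expected = np.zeros((3, 15), int)
        expected[:, 0] = 2
        expected[:, 3] = 1
        assert np.array_equal(sig.counts, expected)

    def test_path_p4_matches_brute_force(self):
        sig = pl.count_orbits(nx.path_graph(4))
        assert np.array_equal(sig.counts, brute_force_orbits(nx.path_graph(4)))
        # end nodes occupy orbit 4, middles orbit 5 in the single P4
        assert sig.counts[0, 4] == 1 and sig.counts[1, 5] == 1

    def test_random_graphs_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.8)),
                                    seed=int(rng.integers(2 ** 31)))
            assert np.array_equal(pl.count_orbits(g).counts,
                                  brute_force_orbits(g))

    def test_handshake_identity(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        sig = pl.count_orbits(g)
        assert sig.counts[:, 0].sum() == 2 * g.number_of_edges()

    def test_self_loops_rejected(self):
        g = nx.Graph([(0, 0), (0, 1)])
        with pytest.raises(ValueError):
            pl.count_orbits(g)


class TestGraphletCorrelation:
    def test_gcm_shape_diagonal_symmetry(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        gcm = pl.graphlet_correlation_matrix(pl.count_orbits(g))
        assert gcm.shape == (11, 11)
        assert np.allclose(np.diag(gcm), 1.0)
        assert np.allclose(gcm, gcm.T)

    def test_regular_graph_co_constant_orbits_via_dummy_row(self):
        # in K4 every node is equivalent: within the 11-orbit subset only
        # degree is nonzero, all columns constant; the dummy ones row makes
        # every pairwise correlation +/-1 by convention
        gcm = pl.graphlet_correlation_matrix(pl.count_orbits(nx.complete_graph(4)))
        assert np.allclose(np.abs(gcm), 1.0)

    def test_gcd_identity_symmetry_and_oracle_value(self):
        k6, p6 = nx.complete_graph(6), nx.path_graph(6)
        a = pl.graphlet_correlation_matrix(pl.count_orbits(k6))
        b = pl.graphlet_correlation_matrix(pl.count_orbits(p6))
        assert pl.gcd(a, a) == 0.0
        assert pl.gcd(a, b) == pl.gcd(b, a)
        iu = np.triu_indices(11, 1)
        oracle = float(np.sqrt(((a - b)[iu] ** 2).sum()))
        assert pl.gcd(a, b) == pytest.approx(oracle)
        assert pl.gcd(a, b) > 0


class TestEmbedding:
    def test_equidistant_networks_form_equilateral_triangle(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        coords = pl.embed_networks(D)
        dists = [np.linalg.norm(coords[i] - coords[j])
                 for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, 2.0, atol=1e-8)

    def test_duplicate_network_coincident(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        coords = pl.embed_networks(D)
        assert np.allclose(coords[0], coords[1], atol=1e-8)

    def test_embedding_correlates_with_input_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 5))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        coords = pl.embed_networks(D, n_dim=2)
        De = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        iu = np.triu_indices(8, 1)
        assert np.corrcoef(D[iu], De[iu])[0, 1] >= 0.9


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        assert pl.natural_connectivity(nx.empty_graph(5)) == 0.0

    def test_k3_closed_form(self):
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert pl.natural_connectivity(nx.complete_graph(3)) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(4)
        for n in (20, 80, 200):
            g = nx.gnp_random_graph(n, 3.0 / n, seed=int(rng.integers(2**31)))
            lam = np.linalg.eigvalsh(nx.to_numpy_array(g))
            direct = np.log(np.mean(np.exp(lam)))
            assert pl.natural_connectivity(g) == pytest.approx(direct, abs=1e-9)

    def test_adding_edge_strictly_increases(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            before = pl.natural_connectivity(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[rng.integers(len(non_edges))]
            g.add_edge(u, v)
            assert pl.natural_connectivity(g) > before

    def test_empty_node_set_is_error(self):
        with pytest.raises(ValueError):
            pl.natural_connectivity(nx.Graph())


class TestAttacks:
    def test_star_degree_attack_collapses_after_hub(self):
        curve = pl.attack_curve(nx.star_graph(10), "degree")
        assert curve.connectivity[0] > 0
        assert curve.connectivity[1] == 0.0

    def test_star_targeted_below_random_mean(self):
        star = nx.star_graph(12)
        deg = pl.attack_curve(star, "degree")
        rand = pl.attack_curve(star, "random", n_rep=50, seed=0)
        assert np.all(deg.connectivity <= rand.connectivity + 1e-12)

    def test_random_attack_reproducible(self):
        g = nx.gnp_random_graph(15, 0.3, seed=0)
        a = pl.attack_curve(g, "random", n_rep=5, seed=42)
        b = pl.attack_curve(g, "random", n_rep=5, seed=42)
        assert np.array_equal(a.connectivity, b.connectivity)


class TestSummariesAndKeystones:
    def test_path_diameter_and_k4_modularity(self):
        assert pl.summary_stats(nx.path_graph(4))["diameter"] == 3
        assert pl.summary_stats(nx.complete_graph(4))["modularity"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_phylum_cliques_perfectly_assortative(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        for u in g.nodes():
            g.nodes[u]["phylum"] = "A" if u < 4 else "B"
        assert pl.summary_stats(g)["phylum_assortativity"] == pytest.approx(1.0)

    def test_star_center_is_unique_keystone(self):
        ks = pl.top_keystones(nx.star_graph(8), k=1)
        assert ks[0]["otu"] == 0

    def test_barbell_bridge_outranks_clique_members(self):
        g = nx.barbell_graph(5, 1)  # two K5s joined through one bridge node
        ks = pl.top_keystones(g, k=3)
        bet = dict(zip([k["otu"] for k in ks], [k["betweenness"] for k in ks]))
        bridge = 5  # the path node between the cliques
        assert bridge in bet
        assert bet[bridge] == max(k["betweenness"] for k in ks)

    def test_k_larger_than_node_count_returns_all(self):
        assert len(pl.top_keystones(nx.path_graph(3), k=10)) == 3


class TestOrbitRedundancy:
    def test_nonredundant_set_has_exactly_eleven_members(self):
        assert len(NONREDUNDANT_ORBITS) == 11
        res = pl.nettopo.verify_nonredundant_orbits(seed=0, n_graphs=25)
        assert res["nonredundant_count"] == 11
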