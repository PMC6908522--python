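"""Similarity, clustering-coefficient thresholding, CCPs and hub ranking."""

import itertools

import numpy as np
import pytest

from coexmeta.errors import ConfigurationError, NetworkError
from coexmeta.network import (GeneNetwork, SimilarityMatrix, build_network,
                              ccp_intersection, clustering_coefficient,
                              connected_components, expected_random_cc,
                              hub_rank, select_threshold, similarity_matrix,
                              threshold_scan)
from coexmeta.simulate import SimulationConfig, gen_coexpression_pair

from conftest import make_study


def net(edges, nodes=None):
    edges = {tuple(sorted(e)) for e in edges}
    nodes = set(nodes) if nodes else {v for e in edges for v in e}
    return GeneNetwork(nodes=nodes, edges=edges)


def sim_from(labels, matrix):
    return SimilarityMatrix(labels=list(labels), values=np.asarray(matrix, float))


def brute_force_cc(network):
    """Independent mean-local-clustering enumeration (triangle counting)."""
    adj = {v: set() for v in network.nodes}
    for a, b in network.edges:
        adj[a].add(b)
        adj[b].add(a)
    locals_ = []
    for v, nb in adj.items():
        k = len(nb)
        if k < 2:
            continue
        tri = sum(1 for x, y in itertools.combinations(nb, 2) if y in adj[x])
        locals_.append(2 * tri / (k * (k - 1)))
    return float(np.mean(locals_)) if locals_ else 0.0


class TestSimilarity:
    def test_matches_textbook_pearson(self, rng):
        x = rng.normal(size=(3, 5))
        study = make_study(x, ["control", "control", "case", "case", "case"],
                           samples=[f"s{j}" for j in range(5)])
        sim = similarity_matrix(study)
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
                assert sim.values[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_anticorrelation_maps_to_one(self):
        x = np.array([[1.0, 2, 3, 4], [-1.0, -2, -3, -4], [4.0, 3, 2, 1]])
        study = make_study(x, ["control", "control", "case", "case"])
        sim = similarity_matrix(study)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(1.0)

    def test_zero_variance_genes_dropped(self, rng):
        x = rng.normal(size=(4, 6))
        x[2] = 5.0
        study = make_study(x, ["control"] * 3 + ["case"] * 3)
        sim = similarity_matrix(study)
        assert "g2" not in sim.labels and len(sim.labels) == 3

    def test_too_few_usable_genes_rejected(self, rng):
        study = make_study(rng.normal(size=(5, 6)), ["control"] * 3 + ["case"] * 3)
        with pytest.raises(NetworkError):
            similarity_matrix(study, gene_subset=["g0"])


class TestClusteringCoefficient:
    def test_triangle_is_one(self):
        assert clustering_coefficient(net([("A", "B"), ("B", "C"), ("A", "C")])) == 1.0

    def test_square_is_zero(self):
        assert clustering_coefficient(
            net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])) == 0.0

    def test_triangle_with_pendant(self):
        g = net([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D")])
        assert clustering_coefficient(g) == pytest.approx(7 / 9)

    def test_exhaustive_small_graphs_match_brute_force(self):
        """Every labeled graph on up to 5 nodes, plus random 6-8 node graphs."""
        for n in range(2, 6):
            pairs = list(itertools.combinations([f"v{i}" for i in range(n)], 2))
            for bits in range(2 ** len(pairs)):
                edges = {pairs[i] for i in range(len(pairs)) if bits >> i & 1}
                g = GeneNetwork(nodes={f"v{i}" for i in range(n)}, edges=edges)
                assert clustering_coefficient(g) == pytest.approx(
                    brute_force_cc(g), abs=1e-12)
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(6, 9))
            pairs = list(itertools.combinations([f"v{i}" for i in range(n)], 2))
            mask = rng.random(len(pairs)) < rng.uniform(0.2, 0.8)
            g = GeneNetwork(nodes={f"v{i}" for i in range(n)},
                            edges={p for p, m in zip(pairs, mask) if m})
            assert clustering_coefficient(g) == pytest.approx(
                brute_force_cc(g), abs=1e-12)


class TestRandomCc:
    def test_closed_form(self):
        assert expected_random_cc(10, 9) == pytest.approx(0.2)

    def test_degenerate_cases(self):
        assert expected_random_cc(5, 0) == 0.0
        assert expected_random_cc(5, 10) == 1.0  # complete K5

    def test_too_many_edges_rejected(self):
        with pytest.raises(NetworkError):
            expected_random_cc(4, 7)


class TestThresholding:
    def test_monotone_filtration(self, rng):
        a = rng.uniform(0, 1, size=(20, 20))
        sim = sim_from([f"g{i}" for i in range(20)],
                       np.clip((a + a.T) / 2, 0, 1) * (1 - np.eye(20)) + np.eye(20))
        taus = [0.2, 0.4, 0.6, 0.8]
        nets = [build_network(sim, t) for t in taus]
        for lo, hi in zip(nets, nets[1:]):
            assert hi.edges <= lo.edges

    def test_tau_zero_is_complete_graph(self, rng):
        x = rng.normal(size=(5, 10))
        study = make_study(x, ["control"] * 5 + ["case"] * 5)
        netw = build_network(similarity_matrix(study), 0.0)
        assert netw.n_edges == 10  # C(5,2)

    def test_block_diagonal_sim_flat_excess(self):
        labels = [f"g{i}" for i in range(6)]
        m = np.zeros((6, 6))
        m[:3, :3] = 1.0
        m[3:, 3:] = 1.0
        sim = sim_from(labels, m)
        scan = threshold_scan(sim)
        d = scan.excess_cc
        assert np.allclose(d, d[0])
        assert select_threshold(scan, min_edges=1) == pytest.approx(0.5)

    def test_unimodal_excess_peak_selected(self):
        cfg = SimulationConfig(n_genes=150, n_blocks=5, block_size=20,
                               within_block_r=0.8, between_block_r=0.1, seed=7)
        study, _, truth = gen_coexpression_pair(cfg)
        sim = similarity_matrix(study)
        scan = threshold_scan(sim)
        tau = select_threshold(scan)
        assert 0.1 < tau < 0.8  # peak lies between the two correlation levels

    def test_planted_block_edges_recovered(self):
        cfg = SimulationConfig(n_genes=150, n_blocks=5, block_size=20,
                               within_block_r=0.8, between_block_r=0.1, seed=7)
        study, _, truth = gen_coexpression_pair(cfg)
        sim = similarity_matrix(study)
        tau = select_threshold(threshold_scan(sim))
        netw = build_network(sim, tau)
        planted = truth.within_block_edges()
        jac = len(netw.edges & planted) / len(netw.edges | planted)
        assert jac >= 0.8

    def test_min_edges_guard(self):
        sim = sim_from(["a", "b"], [[1.0, 0.1], [0.1, 1.0]])
        with pytest.raises(NetworkError, match="min_edges"):
            select_threshold(threshold_scan(sim), min_edges=10)


class TestCcp:
    def test_idempotent_on_identical_networks(self):
        g = net([("a", "b"), ("b", "c"), ("c", "d")])
        ccp = ccp_intersection(g, g)
        assert ccp.edges == g.edges and ccp.nodes == g.nodes

    def test_worked_fixture(self):
        a = net([("a", "b"), ("b", "c"), ("c", "d")])
        b = net([("b", "c"), ("c", "d"), ("d", "e")])
        ccp = ccp_intersection(a, b)
        assert ccp.nodes == {"b", "c", "d"}
        assert ccp.edges == {("b", "c"), ("c", "d")}

    def test_disjoint_edge_sets_empty(self):
        a, b = net([("a", "b")]), net([("c", "d")])
        ccp = ccp_intersection(a, b)
        assert (ccp.n_nodes, ccp.n_edges) == (0, 0)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            names = [f"v{i}" for i in range(n)]
            def random_net():
                edges = set()
                for _ in range(int(rng.integers(0, 3 * n))):
                    i, j = rng.choice(n, 2, replace=False)
                    edges.add(tuple(sorted((names[i], names[j]))))
                return GeneNetwork(nodes=set(names), edges=edges)
            a, b = random_net(), random_net()
            ccp = ccp_intersection(a, b)
            brute = {e for e in a.edges if e in b.edges}
            assert ccp.edges == brute
            assert ccp.nodes == {v for e in brute for v in e}
            assert ccp.n_edges <= min(a.n_edges, b.n_edges)
            # commutativity and associativity
            assert ccp_intersection(b, a).edges == ccp.edges
            c = random_net()
            lhs = ccp_intersection(ccp_intersection(a, b), c).edges
            rhs = ccp_intersection(a, ccp_intersection(b, c)).edges
            assert lhs == rhs

    def test_component_enumeration(self):
        g = net([("a", "b"), ("c", "d"), ("d", "e")])
        comps = connected_components(g)
        assert [len(c) for c in comps] == [3, 2]


class TestHubRank:
    def test_star_center_first(self):
        g = net([("hub", x) for x in "abcd"])
        assert hub_rank(g).index[0] == "hub"

    def test_triangle_tie_alphabetical(self):
        g = net([("x", "y"), ("y", "z"), ("x", "z")])
        assert list(hub_rank(g).index) == ["x", "y", "z"]

    def test_top_k_and_guard(self):
        g = net([("a", "b"), ("b", "c")])
        assert len(hub_rank(g, top_k=2)) == 2
        with pytest.raises(ConfigurationError):
            hub_rank(g, top_k=0)

    def test_planted_hub_recovered(self):
        rng = np.random.default_rng(21)
        n = 40
        x = rng.normal(size=(n, 30))
        x[0] = rng.normal(size=30)
        for i in range(1, 15):
            x[i] = x[0] + rng.normal(0, 0.4, size=30)  # spokes follow gene 0
        study = make_study(x, ["control"] * 15 + ["case"] * 15)
        sim = similarity_matrix(study)
        netw = build_network(sim, 0.75)
        assert hub_rank(netw).index[0] == "g0"
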