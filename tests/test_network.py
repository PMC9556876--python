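"""Neighborhood construction, pruning, ECC, adaptive threshold, double filter."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pfpgo.network import (
    NeighborhoodGraph,
    adaptive_threshold,
    classify_nonessential,
    double_filter,
    edge_clustering_coefficient,
    neighborhood,
    prune_nonessential,
    refine_neighborhood,
)


def ecc_bruteforce(g, u, v):
    """Independent oracle: count triangles through the edge explicitly."""
    triangles = sum(1 for w in g.nodes() if w not in (u, v)
                    and g.has_edge(u, w) and g.has_edge(v, w))
    denom = min(g.degree(u) - 1, g.degree(v) - 1)
    return triangles / denom if denom > 0 else 0.0


class TestNeighborhood:
    def test_path_levels(self):
        net = nx.path_graph(["a", "b", "c", "d"])
        ng = neighborhood(net, "a")
        assert ng.nodes == {"a", "b", "c"}
        assert ng.level == {"b": 1, "c": 2}

    def test_isolated_target(self):
        net = nx.Graph()
        net.add_node("a")
        ng = neighborhood(net, "a")
        assert ng.nodes == {"a"} and ng.level == {}

    def test_absent_target_errors(self):
        with pytest.raises(ValueError):
            neighborhood(nx.path_graph(3), "zz")

    def test_matches_distance_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            g = nx.gnp_random_graph(50, 0.08, seed=int(rng.integers(2**31)))
            target = 0
            # oracle: adjacency-power reachability within two hops
            a = nx.to_numpy_array(g, nodelist=sorted(g), dtype=bool)
            two_hop = a | (a @ a)
            expected = {n for n in g if two_hop[target, n]} | {target}
            ng = neighborhood(g, target)
            assert ng.nodes == expected
            # all induced edges retained, including level-2 <-> level-2
            assert set(map(frozenset, ng.graph.edges())) == {
                frozenset(e) for e in g.subgraph(expected).edges()
            }


class TestECC:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert edge_clustering_coefficient(g, 0, 1) == 1.0

    def test_square_has_no_shared_neighbors(self):
        g = nx.cycle_graph(4)
        assert edge_clustering_coefficient(g, 0, 1) == 0.0

    def test_mixed_fixture(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e")])
        assert edge_clustering_coefficient(g, "b", "c") == 1.0
        assert edge_clustering_coefficient(g, "c", "d") == 0.0

    def test_exhaustive_small_graphs(self):
        # every labeled simple graph on <= 5 nodes
        nodes = range(5)
        possible = list(itertools.combinations(nodes, 2))
        for mask in range(2 ** len(possible)):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(e for i, e in enumerate(possible) if mask >> i & 1)
            for u, v in g.edges():
                got = edge_clustering_coefficient(g, u, v)
                assert got == pytest.approx(ecc_bruteforce(g, u, v))
                assert 0.0 <= got <= 1.0

    def test_atlas_and_random_graphs(self):
        from networkx.generators.atlas import graph_atlas_g

        for g in graph_atlas_g()[1:]:  # all non-isomorphic graphs, <= 7 nodes
            for u, v in g.edges():
                assert edge_clustering_coefficient(g, u, v) == pytest.approx(
                    ecc_bruteforce(g, u, v))
        rng = np.random.default_rng(6)
        for _ in range(10):
            g = nx.gnp_random_graph(50, 0.1, seed=int(rng.integers(2**31)))
            for u, v in g.edges():
                assert edge_clustering_coefficient(g, u, v) == pytest.approx(
                    ecc_bruteforce(g, u, v))


class TestClassify:
    def _ng(self, edges, target):
        g = nx.Graph(edges)
        return NeighborhoodGraph(target=target, graph=g)

    def test_star_center_is_bridge(self):
        ng = self._ng([("c", x) for x in "abt"], target="t")
        assert classify_nonessential(ng, "c") == "bridge"

    def test_leaf_is_shore(self):
        ng = self._ng([("t", "a"), ("t", "b"), ("a", "b"), ("a", "x")], target="t")
        assert classify_nonessential(ng, "x") == "shore"

    def test_triangle_free_connector_is_fjord(self):
        # b has degree 2, no triangles, but is not an articulation point
        edges = [("t", "a"), ("t", "c"), ("a", "b"), ("b", "c"),
                 ("t", "d"), ("d", "a"), ("d", "c")]
        ng = self._ng(edges, target="t")
        g = ng.graph
        assert "b" not in set(nx.articulation_points(g))
        assert nx.triangles(g, "b") == 0 and g.degree("b") == 2
        assert classify_nonessential(ng, "b") == "fjord"

    def test_embedded_node_is_none(self):
        ng = self._ng(list(itertools.combinations("tabc", 2)), target="t")
        assert classify_nonessential(ng, "a") == "none"

    def test_target_classification_errors(self):
        ng = self._ng([("t", "a")], target="t")
        with pytest.raises(ValueError):
            classify_nonessential(ng, "t")


class TestPrune:
    def test_all_leaves_pruned_target_survives(self):
        ng = NeighborhoodGraph("t", nx.Graph([("t", f"x{i}") for i in range(5)]))
        out = prune_nonessential(ng)
        assert out.nodes == {"t"}

    def test_clique_unchanged(self):
        g = nx.complete_graph(5)
        ng = NeighborhoodGraph(0, g.copy())
        out = prune_nonessential(ng)
        assert out.nodes == set(g.nodes())

    def test_simultaneous_removal_matches_label_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = nx.gnp_random_graph(15, 0.2, seed=int(rng.integers(2**31)))
            if 0 not in g:
                g.add_node(0)
            ng = NeighborhoodGraph(0, g.copy())
            arts = set(nx.articulation_points(g))
            expected_removed = set()
            for n in g.nodes():
                if n == 0:
                    continue
                if (n in arts or g.degree(n) == 1
                        or (g.degree(n) >= 2 and nx.triangles(g, n) == 0)):
                    expected_removed.add(n)
            out = prune_nonessential(ng)
            assert out.nodes == set(g.nodes()) - expected_removed


class TestAdaptiveThreshold:
    def test_zero_variance_collapses_to_mean(self):
        assert adaptive_threshold([0.4] * 10, k=3) == pytest.approx(0.4)

    @pytest.mark.parametrize("alpha,sigma,k,expected", [
        (0.5, 0.2, 3, 0.5 + 0.6 * (1 - 1 / 1.04)),   # ~0.523077
        (0.0, 1.0, 3, 1.5),
    ])
    def test_closed_form_examples(self, alpha, sigma, k, expected):
        # two-point population with the requested mean and SD
        values = [alpha - sigma, alpha + sigma]
        assert adaptive_threshold(values, k=k) == pytest.approx(expected, abs=1e-12)

    def test_never_below_mean(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            values = rng.normal(size=rng.integers(1, 30))
            thr = adaptive_threshold(values, k=3)
            assert thr >= np.mean(values) - 1e-12
            if np.std(values) > 0:
                assert thr > np.mean(values)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            adaptive_threshold([])


class TestDoubleFilter:
    def test_uniform_graph_is_noop(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 0.8, "weight")
        ng = NeighborhoodGraph(0, g.copy())
        out = double_filter(ng)
        assert set(out.graph.edges()) == set(g.edges())

    def test_clique_with_pendant_chain(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        nx.set_edge_attributes(g, 0.9, "weight")
        g.add_edge("d", "e", weight=0.1)
        g.add_edge("e", "f", weight=0.1)
        ng = NeighborhoodGraph("a", g.copy())
        out = double_filter(ng)
        # chain edges have ECC 0 (below threshold); clique edges have ECC 1
        assert set(map(frozenset, out.graph.edges())) == {
            frozenset(e) for e in nx.complete_graph(["a", "b", "c", "d"]).edges()
        }
        assert "e" not in out.nodes and "f" not in out.nodes

    def test_monotone_and_target_survives(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = nx.gnp_random_graph(20, 0.15, seed=int(rng.integers(2**31)))
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.random())
            if 0 not in g:
                g.add_node(0)
            ng = NeighborhoodGraph(0, g.copy())
            pruned = prune_nonessential(ng)
            out = double_filter(pruned)
            assert 0 in out.nodes
            assert out.graph.number_of_nodes() <= pruned.graph.number_of_nodes() <= g.number_of_nodes()
            assert out.graph.number_of_edges() <= pruned.graph.number_of_edges() <= g.number_of_edges()
            assert set(out.graph.edges()) <= set(pruned.graph.edges())


class TestRefineDeterminism:
    def test_identical_inputs_identical_outputs(self, world):
        target = world.targets[0]
        a, ra = refine_neighborhood(world.network, target)
        b, rb = refine_neighborhood(world.network, target)
        assert ra == rb
        assert set(a.graph.edges()) == set(b.graph.edges())
        assert a.level == b.level
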