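"""Degree-seeded property-space clustering and sequence-based prediction."""

import networkx as nx
import numpy as np
import pytest

from pfpgo.network import NeighborhoodGraph
from pfpgo.physchem import compute_properties
from pfpgo.seq_predictor import (
    assign_target,
    build_clusters,
    sequence_predict,
    validate_clusters,
    Cluster,
)


def _ng(edges, target, extra_nodes=()):
    g = nx.Graph(edges)
    g.add_nodes_from(extra_nodes)
    return NeighborhoodGraph(target=target, graph=g)


def _two_clique_fixture():
    """Two disconnected cliques with well-separated property profiles."""
    left = [f"a{i}" for i in range(3)]
    right = [f"b{i}" for i in range(3)]
    edges = [(u, v) for i, u in enumerate(left) for v in left[i + 1:]]
    edges += [(u, v) for i, u in enumerate(right) for v in right[i + 1:]]
    ng = _ng(edges, target="t", extra_nodes=["t"])
    zvecs = {n: np.full(7, 0.0) + i * 0.01 for i, n in enumerate(left)}
    zvecs.update({n: np.full(7, 5.0) + i * 0.01 for i, n in enumerate(right)})
    return ng, zvecs, left, right


class TestBuildClusters:
    def test_planted_cliques_recovered(self):
        ng, zvecs, left, right = _two_clique_fixture()
        clusters = build_clusters(ng, zvecs, dist_threshold=1.0)
        got = sorted(sorted(c.members) for c in clusters)
        assert got == [sorted(left), sorted(right)]

    def test_partition_property(self):
        rng = np.random.default_rng(14)
        g = nx.gnp_random_graph(20, 0.2, seed=20)
        ng = NeighborhoodGraph(target=0, graph=g)
        zvecs = {n: rng.normal(size=7) for n in g.nodes() if n != 0}
        clusters = build_clusters(ng, zvecs)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(n for n in g.nodes() if n != 0)
        assert len(set(members)) == len(members)

    def test_identical_properties_first_seed_absorbs_neighbors(self):
        g = nx.star_graph(4)  # node 0 is the hub
        g.add_node("t")
        ng = NeighborhoodGraph(target="t", graph=g)
        zvecs = {n: np.zeros(7) for n in g.nodes() if n != "t"}
        clusters = build_clusters(ng, zvecs, dist_threshold=0.5)
        assert sorted(clusters[0].members) == [0, 1, 2, 3, 4]
        assert clusters[0].seed == 0

    def test_missing_vector_errors(self):
        ng = _ng([("a", "b")], target="t", extra_nodes=["t"])
        with pytest.raises(ValueError, match="'b'"):
            build_clusters(ng, {"a": np.zeros(7)}, dist_threshold=1.0)

    def test_seed_has_max_degree(self):
        ng, zvecs, left, right = _two_clique_fixture()
        for cluster in build_clusters(ng, zvecs, dist_threshold=1.0):
            degrees = {m: ng.graph.degree(m) for m in cluster.members}
            assert degrees[cluster.seed] == max(degrees.values())


class TestValidateClusters:
    def test_separated_clusters_clean(self):
        ng, zvecs, _, _ = _two_clique_fixture()
        clusters = build_clusters(ng, zvecs, dist_threshold=1.0)
        report = validate_clusters(clusters, zvecs)
        assert report["warnings"] == []
        assert report["n_clusters"] == 2

    def test_single_cluster_vacuously_valid(self):
        c = Cluster(seed="a", members=["a"], score_vector=np.zeros(7))
        report = validate_clusters([c], {"a": np.zeros(7)})
        assert report["warnings"] == [] and report["n_clusters"] == 1
        assert "max_intra" in report and "min_inter_centroid" in report


class TestAssignTarget:
    def test_exact_centroid_match(self):
        a = Cluster("a", ["a"], score_vector=np.zeros(7))
        b = Cluster("b", ["b"], score_vector=np.ones(7))
        assert assign_target(np.zeros(7), [a, b]) is a

    def test_tie_broken_by_seed_id(self):
        a = Cluster("s2", ["s2"], score_vector=np.ones(7))
        b = Cluster("s1", ["s1"], score_vector=-np.ones(7))
        assert assign_target(np.zeros(7), [a, b]).seed == "s1"

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            clusters = [
                Cluster(f"s{i}", [f"s{i}"], score_vector=rng.normal(size=7))
                for i in range(6)
            ]
            tz = rng.normal(size=7)
            best = min(
                clusters,
                key=lambda c: (np.linalg.norm(tz - c.score_vector), c.seed),
            )
            assert assign_target(tz, clusters) is best


class TestSequencePredict:
    def test_nearest_member_terms_transferred_with_equal_scores(self, world):
        target = world.targets[0]
        from pfpgo.network import refine_neighborhood
        from pfpgo.annotations import node_term_map
        from pfpgo.pipeline import full_annotation_table

        table = full_annotation_table(world).without_proteins(
            world.idmap.lookup(target))
        node_terms = node_term_map(table, idmap=world.idmap,
                                   nodes=world.network.nodes())
        props = {r.id: compute_properties(r.sequence) for r in world.sequences}
        refined, _ = refine_neighborhood(world.network, target)
        got = sequence_predict(target, refined, props, node_terms)
        assert got, "planted world target should receive a prediction"
        scores = {s for _, s in got}
        assert len(scores) == 1 and 0 < scores.pop() <= 1.0
        # never invents terms outside the neighborhood's annotations
        neighborhood_terms = set().union(
            *(node_terms.get(n, frozenset()) for n in refined.members()))
        assert {t for t, _ in got} <= neighborhood_terms

    def test_zero_distance_scores_one(self):
        g = nx.complete_graph(["t", "a", "b", "c"])
        ng = NeighborhoodGraph(target="t", graph=g)
        vec = compute_properties("MKWVTAGHILMKWVTAGHIL")
        other = compute_properties("DDDDEEEEKKKKRRRRDDEE")
        props = {"t": vec, "a": vec, "b": other, "c": other}
        node_terms = {"a": frozenset({"t1", "t2"})}
        got = sequence_predict("t", ng, props, node_terms, dist_threshold=1e6)
        assert got == [("t1", 1.0), ("t2", 1.0)]

    def test_planted_module_term_recovered(self, world):
        from pfpgo.pipeline import predict_world

        target = world.targets[0]
        preds, _ = predict_world(world, targets=[target])
        seq_terms = set(preds.predictions["seq"][target])
        assert seq_terms & set(world.truth[target])


def test_scalar_mode_transfers_from_scalar_nearest(world):
    from pfpgo.network import refine_neighborhood
    from pfpgo.annotations import node_term_map
    from pfpgo.pipeline import full_annotation_table

    target = world.targets[0]
    table = full_annotation_table(world).without_proteins(
        world.idmap.lookup(target))
    node_terms = node_term_map(table, idmap=world.idmap,
                               nodes=world.network.nodes())
    props = {r.id: compute_properties(r.sequence) for r in world.sequences}
    refined, _ = refine_neighborhood(world.network, target)
    got = sequence_predict(target, refined, props, node_terms, scalar_mode=True)
    assert got and all(0 < s <= 1 for _, s in got)
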