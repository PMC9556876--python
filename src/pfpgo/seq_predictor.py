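"""Sequence-based GO prediction via degree-seeded clustering in property space.

Refined-neighborhood proteins are clustered greedily: the unassigned node of
highest degree seeds a cluster and absorbs its still-unassigned direct graph
neighbors whose Euclidean distance in z-scored 7-property space falls below
a threshold. The target is assigned to the nearest cluster (by centroid) and
inherits the GO terms of the single nearest cluster member, scored
``1 / (1 + distance)``.

The default admission threshold reuses the pipeline's adaptive threshold
(``alpha + k*sigma*(1 - 1/(1+sigma^2))``) over all pairwise member distances.
All ties are broken by id ascending, so the predictor is independent of node
iteration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np

from .network import NeighborhoodGraph, adaptive_threshold
from .physchem import PropertyVector, standardize_population, zscore_vector

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A seed-rooted cluster of neighborhood proteins (seed first)."""

    seed: str
    members: list[str]
    score_vector: np.ndarray = field(default_factory=lambda: np.zeros(7))
    score_scalar: float = 0.0


def _distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def build_clusters(
    g: NeighborhoodGraph,
    zvecs: Mapping[str, np.ndarray],
    dist_threshold: float | None = None,
    k: float = 3,
) -> list[Cluster]:
    """Greedy degree-seeded clustering of the non-target neighborhood nodes.

    Clusters partition the clusterable nodes (disjoint, exhaustive);
    singletons are permitted.
    """
    nodes = g.members()
    for node in nodes:
        if node not in zvecs:
            raise ValueError(f"missing property vector for node {node!r}")
    if dist_threshold is None:
        pair_dists = [
            _distance(zvecs[a], zvecs[b]) for a, b in combinations(nodes, 2)
        ]
        dist_threshold = adaptive_threshold(pair_dists, k) if pair_dists else 0.0

    pool = set(nodes)
    clusters: list[Cluster] = []
    while pool:
        seed = min(pool, key=lambda n: (-g.graph.degree(n), n))
        members = [seed]
        for nb in sorted(g.graph.neighbors(seed)):
            if nb in pool and nb != seed and nb != g.target:
                if _distance(zvecs[nb], zvecs[seed]) < dist_threshold:
                    members.append(nb)
        pool.difference_update(members)
        mat = np.vstack([zvecs[m] for m in members])
        clusters.append(
            Cluster(
                seed=seed,
                members=members,
                score_vector=mat.mean(axis=0),
                score_scalar=float(mat.mean()),
            )
        )
    return clusters


def validate_clusters(
    clusters: list[Cluster], zvecs: Mapping[str, np.ndarray]
) -> dict:
    """Intra- vs inter-cluster separation report.

    A warning entry is emitted for every cluster whose maximum intra-cluster
    distance reaches or exceeds the minimum inter-centroid distance (possible
    overlap / misclassification); validation never fails hard.
    """
    max_intra = {}
    for cluster in clusters:
        dists = [
            _distance(zvecs[a], zvecs[b])
            for a, b in combinations(cluster.members, 2)
        ]
        max_intra[cluster.seed] = max(dists) if dists else 0.0
    centroid_dists = [
        _distance(a.score_vector, b.score_vector)
        for a, b in combinations(clusters, 2)
    ]
    min_inter = min(centroid_dists) if centroid_dists else float("inf")
    warnings = [
        f"cluster {seed!r}: max intra-cluster distance {intra:.4g} >= "
        f"min inter-centroid distance {min_inter:.4g}"
        for seed, intra in max_intra.items()
        if intra >= min_inter
    ]
    for msg in warnings:
        logger.warning(msg)
    return {
        "n_clusters": len(clusters),
        "max_intra": max_intra,
        "min_inter_centroid": min_inter,
        "warnings": warnings,
    }


def assign_target(target_zvec: np.ndarray, clusters: list[Cluster]) -> Cluster:
    """Nearest cluster by centroid distance; ties go to the smaller seed id."""
    if not clusters:
        raise ValueError("no clusters to assign the target to")
    return min(
        clusters,
        key=lambda c: (_distance(target_zvec, c.score_vector), c.seed),
    )


def sequence_predict(
    target: str,
    g: NeighborhoodGraph,
    props: Mapping[str, PropertyVector],
    node_terms: Mapping[str, frozenset[str]],
    dist_threshold: float | None = None,
    k: float = 3,
    scalar_mode: bool = False,
) -> list[tuple[str, float]]:
    """Predict GO terms for the target from its nearest cluster member.

    ``props`` maps every neighborhood node (and the target) to its raw
    property vector; standardization uses the non-target members as the
    reference population. ``scalar_mode`` collapses each z-scored vector to
    its mean (the scalar property score) before distances — less
    informative, kept for fidelity experiments. Returns (term, score)
    pairs, score = ``1 / (1 + distance)``; empty when the neighborhood is
    too small or the nearest member carries no annotations.
    """
    members = g.members()
    if len(members) < 2:
        logger.warning("sequence_predict(%s): neighborhood too small (%d members)",
                       target, len(members))
        return []
    missing = [n for n in members if n not in props]
    if missing:
        raise ValueError(f"missing property vector for node {missing[0]!r}")
    zvecs = standardize_population({n: props[n] for n in members})
    if target in props:
        mat = np.vstack([props[n].as_array() for n in sorted(members)])
        mean, std = mat.mean(axis=0), mat.std(axis=0)
        target_z = zscore_vector(props[target], mean, std)
    else:
        raise ValueError(f"missing property vector for target {target!r}")
    if scalar_mode:
        zvecs = {n: np.array([v.mean()]) for n, v in zvecs.items()}
        target_z = np.array([target_z.mean()])

    clusters = build_clusters(g, zvecs, dist_threshold=dist_threshold, k=k)
    if not clusters:
        logger.warning("sequence_predict(%s): no clusters formed", target)
        return []
    chosen = assign_target(target_z, clusters)
    nearest = min(
        chosen.members, key=lambda m: (_distance(target_z, zvecs[m]), m)
    )
    dist = _distance(target_z, zvecs[nearest])
    terms = node_terms.get(nearest, frozenset())
    if not terms:
        logger.info("sequence_predict(%s): nearest member %r has no annotations",
                    target, nearest)
        return []
    score = 1.0 / (1.0 + dist)
    return [(term, score) for term in sorted(terms)]
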