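"""Neighborhood graphs, non-essential-node pruning, and 2-pass edge filtering.

A target's level-2 neighborhood (all nodes within shortest-path distance 2,
with all induced edges) is refined in two stages before prediction:

1. *Pruning* removes topologically non-essential neighbors — bridge
   (articulation vertices), fjord (degree >= 2 connectors participating in
   no triangle) and shore (leaf) nodes — in one simultaneous pass computed
   on the original neighborhood.
2. *Double filtering* removes weak edges in two passes: first edges whose
   edge clustering coefficient (ECC) falls below an adaptive threshold over
   all ECC values, then — on the survivors — edges whose confidence weight
   falls below the same adaptive threshold over the surviving weights.
   Nodes left isolated are dropped; the target always survives.

The adaptive threshold is ``alpha + k*sigma*(1 - 1/(1 + sigma^2))`` with
``alpha`` the mean and ``sigma`` the population standard deviation of the
value set; ``k = 3`` gives a high cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Label = Literal["bridge", "fjord", "shore", "none"]


@dataclass
class NeighborhoodGraph:
    """Target-rooted induced subgraph with per-node level tags (1 or 2)."""

    target: str
    graph: nx.Graph
    level: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    def members(self) -> list[str]:
        """Non-target nodes, id-sorted."""
        return sorted(n for n in self.graph.nodes() if n != self.target)

    def _replace(self, graph: nx.Graph) -> "NeighborhoodGraph":
        return NeighborhoodGraph(
            target=self.target,
            graph=graph,
            level={n: l for n, l in self.level.items() if n in graph},
        )


def neighborhood(net: nx.Graph, target: str, depth: int = 2) -> NeighborhoodGraph:
    """Induced subgraph on all nodes within ``depth`` hops of ``target``."""
    if target not in net:
        raise ValueError(f"target {target!r} not in network")
    dist = nx.single_source_shortest_path_length(net, target, cutoff=depth)
    sub = net.subgraph(dist).copy()
    level = {node: d for node, d in dist.items() if d >= 1}
    return NeighborhoodGraph(target=target, graph=sub, level=level)


def edge_clustering_coefficient(g: nx.Graph, u: str, v: str) -> float:
    """Shared neighbors of (u, v) over ``min(deg u - 1, deg v - 1)``.

    0 by convention when an endpoint has degree 1, so leaf edges never look
    cohesive. Bounded by [0, 1] on simple graphs.
    """
    if not g.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in graph")
    shared = len(set(g[u]) & set(g[v]))
    denom = min(g.degree(u) - 1, g.degree(v) - 1)
    return shared / denom if denom > 0 else 0.0


def classify_nonessential(g: NeighborhoodGraph, node: str,
                          _articulation: set[str] | None = None) -> Label:
    """Label a non-target node as bridge, fjord, shore or none.

    Priority: bridge (articulation vertex) > fjord (degree >= 2, zero
    triangles through the node) > shore (leaf). Isolated or well-embedded
    nodes are "none".
    """
    if node == g.target:
        raise ValueError("the target itself is never classified")
    if node not in g.graph:
        raise ValueError(f"node {node!r} not in neighborhood graph")
    articulation = (_articulation if _articulation is not None
                    else set(nx.articulation_points(g.graph)))
    if node in articulation:
        return "bridge"
    degree = g.graph.degree(node)
    if degree >= 2 and nx.triangles(g.graph, node) == 0:
        return "fjord"
    if degree == 1:
        return "shore"
    return "none"


def prune_nonessential(g: NeighborhoodGraph) -> NeighborhoodGraph:
    """Remove all bridge/fjord/shore nodes in one simultaneous pass.

    Labels are computed on the original graph, then all labeled nodes are
    removed together with their incident edges; the target is never removed.
    """
    articulation = set(nx.articulation_points(g.graph))
    labels = {
        node: classify_nonessential(g, node, _articulation=articulation)
        for node in g.graph.nodes()
        if node != g.target
    }
    removed = [node for node, label in labels.items() if label != "none"]
    counts = {lab: sum(1 for n in removed if labels[n] == lab)
              for lab in ("bridge", "fjord", "shore")}
    logger.info("prune_nonessential(%s): removed %s", g.target, counts)
    pruned = g.graph.copy()
    pruned.remove_nodes_from(removed)
    return g._replace(pruned)


def adaptive_threshold(values: Iterable[float], k: float = 3) -> float:
    """``alpha + k*sigma*(1 - 1/(1 + sigma^2))``; population sigma.

    Collapses to the mean when all values are equal. Always >= the mean,
    strictly above it when sigma > 0 and k > 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("adaptive_threshold requires at least one value")
    alpha = arr.mean()
    sigma = arr.std()  # population standard deviation
    return float(alpha + k * sigma * (1.0 - 1.0 / (1.0 + sigma**2)))


def double_filter(g: NeighborhoodGraph, k: float = 3) -> NeighborhoodGraph:
    """2-pass edge filter: ECC threshold, then edge-weight threshold.

    Pass 1 drops edges with ECC strictly below the adaptive threshold over
    all ECC values; pass 2, on the surviving graph, drops edges with weight
    strictly below the adaptive threshold over the surviving weights.
    Strict ``<`` means a zero-variance population is never emptied. Nodes
    left isolated are dropped, except the target. ECC is not recomputed
    after the weight pass.
    """
    out = g.graph.copy()
    if out.number_of_edges() > 0:
        ecc = {
            (u, v): edge_clustering_coefficient(out, u, v) for u, v in out.edges()
        }
        thr_ecc = adaptive_threshold(ecc.values(), k)
        out.remove_edges_from([e for e, val in ecc.items() if val < thr_ecc])
    if out.number_of_edges() > 0:
        weights = {(u, v): out[u][v].get("weight", 1.0) for u, v in out.edges()}
        thr_w = adaptive_threshold(weights.values(), k)
        out.remove_edges_from([e for e, w in weights.items() if w < thr_w])
    isolated = [n for n in out.nodes() if out.degree(n) == 0 and n != g.target]
    out.remove_nodes_from(isolated)
    logger.info(
        "double_filter(%s): %d -> %d edges, dropped %d isolated node(s)",
        g.target, g.graph.number_of_edges(), out.number_of_edges(), len(isolated),
    )
    return g._replace(out)


def refine_neighborhood(
    net: nx.Graph, target: str, k: float = 3, depth: int = 2
) -> tuple[NeighborhoodGraph, dict]:
    """neighborhood -> prune -> double filter, with a per-stage size report."""
    raw = neighborhood(net, target, depth=depth)
    pruned = prune_nonessential(raw)
    refined = double_filter(pruned, k=k)
    report = {
        "target": target,
        "raw": {"nodes": raw.graph.number_of_nodes(), "edges": raw.graph.number_of_edges()},
        "pruned": {"nodes": pruned.graph.number_of_nodes(), "edges": pruned.graph.number_of_edges()},
        "refined": {"nodes": refined.graph.number_of_nodes(), "edges": refined.graph.number_of_edges()},
    }
    return refined, report
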