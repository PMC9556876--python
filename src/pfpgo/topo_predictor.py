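"""Neighborhood GO enrichment ranking via the one-sided Fisher exact test.

For every GO term carried by the target's (refined) level-1/level-2
neighbors, over-representation in the neighborhood relative to an annotated
background is scored with the hypergeometric upper tail
``P(X >= x)`` — the one-sided Fisher exact test for a 2x2 enrichment table.
Terms are ranked by p ascending; the prediction score is ``1 - p``.

The predictor only needs a node -> term map and therefore runs unchanged on
any gene-level association network (e.g. gene-gene association networks),
not just PPI graphs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .network import NeighborhoodGraph

logger = logging.getLogger(__name__)


def fisher_enrichment_p(x: int, n: int, K: int, N: int) -> float:
    """Upper hypergeometric tail P(X >= x), X ~ Hypergeom(N, K, n).

    ``x`` annotated-with-term neighbors out of ``n`` annotated neighbors,
    against ``K`` term carriers among ``N`` annotated background proteins.
    """
    if not (0 <= x <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent counts: x={x}, n={n}, K={K}, N={N}"
        )
    # sf(x-1) = P(X >= x); exact and log-space-safe inside scipy.
    return float(hypergeom.sf(x - 1, N, K, n))


def topo_predict(
    target: str,
    g: NeighborhoodGraph,
    node_terms: Mapping[str, frozenset[str]],
    background: Iterable[str],
    top_n: int = 10,
    alpha: float | None = None,
    correction: str | None = None,
) -> list[tuple[str, float]]:
    """Rank neighbor GO terms by enrichment p-value; score = 1 - p.

    The target's own annotations never enter the evidence (no leakage).
    ``background`` is the annotation universe, normally all annotated nodes
    of the full input network. Ties in p are broken by higher neighborhood
    count x, then term id. ``alpha`` optionally post-filters to p <= alpha
    (applied to Benjamini-Hochberg-adjusted p when ``correction="bh"``;
    ranking itself always uses raw p).
    """
    if correction not in (None, "bh"):
        raise ValueError("correction must be None or 'bh'")
    neighbors = [n for n in g.members() if node_terms.get(n)]
    # the background must cover the neighborhood's annotated nodes
    annotated_background = {node for node in background if node_terms.get(node)}
    annotated_background.update(neighbors)
    N = len(annotated_background)
    n = len(neighbors)
    if n == 0:
        logger.warning("topo_predict(%s): no annotated neighbors", target)
        return []

    candidates: set[str] = set()
    for node in neighbors:
        candidates |= node_terms[node]

    results = []
    for term in sorted(candidates):
        x = sum(1 for node in neighbors if term in node_terms[node])
        K = sum(1 for node in annotated_background if term in node_terms.get(node, ()))
        p = fisher_enrichment_p(x, n, K, N)
        results.append((p, -x, term))
    results.sort()
    if correction == "bh":
        m = len(results)
        adjusted = [p * m / (i + 1) for i, (p, _, _) in enumerate(results)]
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            adjusted[i] = min(adjusted[i], adjusted[i + 1])
        filter_ps = [min(1.0, q) for q in adjusted]
    else:
        filter_ps = [p for p, _, _ in results]
    ranked = [
        (term, 1.0 - p)
        for (p, _negx, term), fp in zip(results, filter_ps)
        if alpha is None or fp <= alpha
    ]
    return ranked[:top_n]
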