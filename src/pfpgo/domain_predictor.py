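"""Domain-domain-interaction-based GO prediction.

Every node of the refined neighborhood is mapped (through an optional chain
of one-to-many id mappings) to its protein domains. For every surviving edge
(u, v), domain pairs (a in domains(u), b in domains(v)) supported by the
domain-domain interaction table are *validated pairs*. GO terms attached to
the domains participating in validated pairs are counted (one occurrence per
domain instance per validated pair) and ranked by frequency; the top-ranked
terms flow back to the target with score ``frequency / max frequency``.

When a domain has no direct domain->GO link, the GO terms of the proteins
carrying that domain are used as a fallback.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Sequence

from .formats_io import DomainTables, IDMapTable, canonical_pair
from .network import NeighborhoodGraph

logger = logging.getLogger(__name__)


def map_node_ids(node: str, idmaps: Sequence[IDMapTable] | None) -> set[str]:
    """Apply a chain of one-to-many mappings; all hits propagate."""
    ids = {node}
    for idmap in idmaps or ():
        ids = {hit for i in ids for hit in idmap.lookup(i)}
        if not ids:
            return set()
    return ids


def neighborhood_domains(
    g: NeighborhoodGraph,
    tables: DomainTables,
    idmaps: Sequence[IDMapTable] | None = None,
) -> dict[str, set[str]]:
    """Per-node domain sets (union over all mapped ids); unmapped -> empty."""
    out: dict[str, set[str]] = {}
    unmapped = 0
    for node in g.graph.nodes():
        domains: set[str] = set()
        for pid in map_node_ids(node, idmaps):
            domains |= tables.domains_of(pid)
        if not domains:
            unmapped += 1
        out[node] = domains
    if unmapped:
        logger.info("neighborhood_domains(%s): %d node(s) without domains",
                    g.target, unmapped)
    return out


def validated_domain_pairs(
    domains_by_node: Mapping[str, set[str]],
    g: NeighborhoodGraph,
    ddi: set[tuple[str, str]],
) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    """All ((u, v), (a, b)) with edge (u, v), a in domains(u), b in domains(v)
    and (a, b) a known domain-domain interaction (order-insensitive)."""
    validated = set()
    for u, v in g.graph.edges():
        for a in domains_by_node.get(u, ()):
            for b in domains_by_node.get(v, ()):
                if canonical_pair(a, b) in ddi:
                    validated.add((canonical_pair(u, v), canonical_pair(a, b)))
    return validated


def _domain_terms(
    domain: str,
    tables: DomainTables,
    node_terms: Mapping[str, frozenset[str]] | None,
) -> set[str]:
    terms = set(tables.domain_go.get(domain, ()))
    if terms or node_terms is None:
        return terms
    # fallback: annotations of the proteins carrying this domain
    for protein, domains in tables.protein_domains.items():
        if domain in domains:
            terms |= set(node_terms.get(protein, ()))
    return terms


def domain_predict(
    target: str,
    g: NeighborhoodGraph,
    tables: DomainTables,
    node_terms: Mapping[str, frozenset[str]] | None = None,
    idmaps: Sequence[IDMapTable] | None = None,
    top_n: int = 10,
) -> list[tuple[str, float]]:
    """Rank GO terms of validated domains by occurrence frequency.

    A domain occurrence is one (protein, domain) instance in the refined
    neighborhood whose domain participates in at least one validated pair;
    each occurrence contributes each of the domain's GO terms once. Returns
    the ``top_n`` terms (frequency descending, term id ascending) scored
    ``frequency / max frequency``.
    """
    domains_by_node = neighborhood_domains(g, tables, idmaps=idmaps)
    validated = validated_domain_pairs(domains_by_node, g, tables.ddi)
    if not validated:
        logger.warning("domain_predict(%s): no validated domain pairs", target)
        return []
    instances: set[tuple[str, str]] = set()
    for (u, v), (a, b) in validated:
        for node, domain in ((u, a), (u, b), (v, a), (v, b)):
            if domain in domains_by_node.get(node, ()):
                instances.add((node, domain))
    freq: Counter[str] = Counter()
    for _node, domain in instances:
        for term in _domain_terms(domain, tables, node_terms):
            freq[term] += 1
    if not freq:
        logger.warning("domain_predict(%s): validated domains carry no GO terms",
                       target)
        return []
    max_freq = max(freq.values())
    ranked = sorted(freq, key=lambda t: (-freq[t], t))[:top_n]
    return [(term, freq[term] / max_freq) for term in ranked]
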