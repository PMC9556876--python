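"""GO annotation table, term-frequency statistics and target selection.

Annotations are flat (protein, GO term, aspect) triples; no ontology
ancestor closure is applied by default (terms are used as flat labels).
"Functionally active" targets are proteins annotated with the most frequent
GO terms, a fixed fraction of which is sampled as prediction targets.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .formats_io import VALID_ASPECTS, IDMapTable

logger = logging.getLogger(__name__)

Triple = tuple[str, str, str]  # (protein_id, go_id, aspect)


class AnnotationTable:
    """Deduplicated set of (protein, GO term, aspect) triples with indexes."""

    def __init__(self, triples: Iterable[Triple]):
        self.triples: frozenset[Triple] = frozenset(tuple(t) for t in triples)
        for _, _, aspect in self.triples:
            if aspect not in VALID_ASPECTS:
                raise ValueError(f"unknown aspect code {aspect!r}")
        self._by_protein: dict[str, set[Triple]] = {}
        self._by_term: dict[str, set[Triple]] = {}
        for triple in self.triples:
            self._by_protein.setdefault(triple[0], set()).add(triple)
            self._by_term.setdefault(triple[1], set()).add(triple)

    # -- queries ------------------------------------------------------------

    @property
    def proteins(self) -> set[str]:
        return set(self._by_protein)

    @property
    def terms(self) -> set[str]:
        return set(self._by_term)

    def terms_for(self, protein: str, aspect: str | None = None) -> set[str]:
        triples = self._by_protein.get(protein, ())
        return {t for _, t, a in triples if aspect is None or a == aspect}

    def proteins_for(self, term: str, aspect: str | None = None) -> set[str]:
        triples = self._by_term.get(term, ())
        return {p for p, _, a in triples if aspect is None or a == aspect}

    def aspect_counts(self) -> dict[str, int]:
        counts = Counter(a for _, _, a in self.triples)
        return {aspect: counts.get(aspect, 0) for aspect in VALID_ASPECTS}

    def term_aspects(self) -> dict[str, str]:
        """Aspect of each term (terms are assumed aspect-pure, as in GO)."""
        return {t: a for _, t, a in self.triples}

    def with_closure(self, parents: Mapping[str, Iterable[str]]) -> "AnnotationTable":
        """Optional true-path pre-closure: annotate ancestors alongside terms.

        ``parents`` maps a term to its (transitive) ancestor terms; ancestors
        inherit the triple's aspect. Off by default everywhere — the method
        treats GO terms as flat labels.
        """
        triples = set(self.triples)
        for protein, term, aspect in self.triples:
            for ancestor in parents.get(term, ()):
                triples.add((protein, ancestor, aspect))
        return AnnotationTable(triples)

    def without_proteins(self, protein_ids: Iterable[str]) -> "AnnotationTable":
        drop = set(protein_ids)
        return AnnotationTable(t for t in self.triples if t[0] not in drop)

    def __len__(self) -> int:
        return len(self.triples)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and self.triples == other.triples

    def __hash__(self):
        return hash(self.triples)


def term_frequencies(table: AnnotationTable, aspect: str | None = None) -> dict[str, int]:
    """Number of distinct proteins carrying each term (optionally per aspect)."""
    if not len(table):
        raise ValueError("empty annotation table")
    freqs: dict[str, int] = {}
    for term in table.terms:
        n = len(table.proteins_for(term, aspect=aspect))
        if n:
            freqs[term] = n
    return freqs


def top_k_terms(freqs: Mapping[str, int], k: int = 10) -> list[str]:
    """The k most frequent terms, ties broken by term id ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(freqs, key=lambda t: (-freqs[t], t))
    return ranked[:k]


@dataclass
class TargetSet:
    """An ordered, duplicate-free set of prediction targets plus provenance."""

    target_ids: list[str]
    top_k_terms: list[str] = field(default_factory=list)
    fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")

    def __iter__(self):
        return iter(self.target_ids)

    def __len__(self):
        return len(self.target_ids)


def select_targets(
    table: AnnotationTable,
    network: nx.Graph,
    idmap: IDMapTable | None = None,
    k_terms: int = 10,
    fraction: float = 0.20,
    seed: int = 0,
) -> TargetSet:
    """Sample functionally active target proteins.

    Proteins annotated with any of the ``k_terms`` most frequent GO terms are
    mapped into the network's id namespace (all hits of a one-to-many mapping
    are kept; unmappables are dropped and logged), restricted to network
    nodes, and ``ceil(fraction * n)`` of them are sampled uniformly without
    replacement. The function is a pure function of its arguments.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    top = top_k_terms(term_frequencies(table), k_terms)
    annotated = sorted({p for t in top for p in table.proteins_for(t)})

    pool: list[str] = []
    seen: set[str] = set()
    unmapped = 0
    for protein in annotated:
        mapped = idmap.reverse_lookup(protein) if idmap is not None else [protein]
        if idmap is not None and not mapped:
            mapped = idmap.lookup(protein)
        if not mapped:
            unmapped += 1
            continue
        for node in mapped:
            if node in network and node not in seen:
                seen.add(node)
                pool.append(node)
    if unmapped:
        logger.info("select_targets: dropped %d unmappable candidate(s)", unmapped)
    if not pool:
        raise ValueError("empty candidate pool: no annotated protein maps into the network")

    n_sample = math.ceil(fraction * len(pool))
    rng = np.random.default_rng(seed)
    sample = [str(n) for n in rng.choice(pool, size=n_sample, replace=False)]
    # Without-replacement sampling cannot produce duplicates; the dedup pass
    # is kept (and logged) for parity with pipelines that sample with replacement.
    deduped: list[str] = []
    seen.clear()
    for node in sample:
        if node not in seen:
            seen.add(node)
            deduped.append(node)
    if len(deduped) != len(sample):
        logger.info("select_targets: removed %d duplicate(s)", len(sample) - len(deduped))
    return TargetSet(deduped, top_k_terms=top, fraction=fraction, seed=seed)


def node_term_map(
    table: AnnotationTable,
    idmap: IDMapTable | None = None,
    nodes: Iterable[str] | None = None,
    aspect: str | None = None,
) -> dict[str, frozenset[str]]:
    """Per-node GO term sets in the network id namespace.

    When ``idmap`` is given, a node's terms are the union over all of its
    mapped annotation-namespace ids (one-to-many respected). Nodes without
    terms are omitted.
    """
    if nodes is None:
        if idmap is not None:
            nodes = {src for src, _ in idmap.pairs}
        else:
            nodes = table.proteins
    out: dict[str, frozenset[str]] = {}
    for node in nodes:
        ids = idmap.lookup(node) if idmap is not None else [node]
        terms: set[str] = set()
        for pid in ids:
            terms |= table.terms_for(pid, aspect=aspect)
        if terms:
            out[node] = frozenset(terms)
    return out
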