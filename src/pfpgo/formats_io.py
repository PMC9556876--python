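"""Readers and writers for the on-disk formats, plus the ID-mapping layer.

All tabular inputs are tab-separated text; lines starting with ``#`` are
comments. Supported formats:

* weighted edge lists (STRING-style ``proteinA  proteinB  combined_score``);
* protein -> GO annotation tables (``protein_id  go_id  aspect``);
* FASTA sequence files (via Biopython);
* two-column ID-mapping tables (one-to-many allowed in both directions);
* domain tables (protein->domains, domain-domain interactions, domain->GO).

The mapping layer includes a sequence-identity fallback: when an identifier
is absent from the mapping table, reference sequences with >= 90% global
pairwise identity stand in for the missing mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .constants import AMINO_ACIDS

logger = logging.getLogger(__name__)

VALID_ASPECTS = ("BP", "MF", "CC")

_AA_SET = frozenset(AMINO_ACIDS)


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20 canonical uppercase amino-acid letters."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ParseError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise ParseError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IDMapTable:
    """One-to-many identifier mapping between two namespaces."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    direction: str = "source->target"

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str]] = []
        for pair in self.pairs:
            if pair not in seen:
                seen.add(pair)
                unique.append(tuple(pair))
        self.pairs = unique
        self._forward: dict[str, list[str]] = {}
        self._reverse: dict[str, list[str]] = {}
        for src, dst in self.pairs:
            self._forward.setdefault(src, []).append(dst)
            self._reverse.setdefault(dst, []).append(src)

    def lookup(self, source_id: str) -> list[str]:
        """All target ids mapped from ``source_id`` (empty list if absent)."""
        return list(self._forward.get(source_id, []))

    def reverse_lookup(self, target_id: str) -> list[str]:
        return list(self._reverse.get(target_id, []))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DomainTables:
    """Protein->domain assignments, domain-domain interactions, domain->GO links.

    DDI pairs are stored canonically (lexicographically smaller id first);
    homotypic pairs (d, d) are allowed.
    """

    protein_domains: dict[str, set[str]] = field(default_factory=dict)
    ddi: set[tuple[str, str]] = field(default_factory=set)
    domain_go: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.ddi = {canonical_pair(a, b) for a, b in self.ddi}

    def domains_of(self, protein_id: str) -> set[str]:
        return set(self.protein_domains.get(protein_id, ()))

    def interacts(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.ddi


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# TSV plumbing


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(path, weight_column: str | None = None) -> nx.Graph:
    """Read a STRING-style weighted edge list into an undirected graph.

    Duplicate A-B / B-A rows are collapsed keeping the maximum weight;
    self-loops are dropped (count logged). An optional header row is
    detected by a non-numeric weight field; ``weight_column`` selects the
    weight column by name when a header is present (default: third column).
    """
    rows = list(_data_lines(path))
    if not rows:
        raise ParseError(f"{path}: empty edge list")

    weight_idx = 2
    first_lineno, first = rows[0]
    if len(first) < 3:
        raise ParseError(f"{path}:{first_lineno}: expected >= 3 columns")
    header_names = {"weight", "score", "combined_score", "confidence"}
    header = (weight_column is not None and weight_column in first) or (
        first[2].lower() in header_names
    )
    if header:
        if weight_column is not None:
            weight_idx = first.index(weight_column)
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: edge list has a header but no data rows")

    g = nx.Graph()
    self_loops = 0
    for lineno, fields in rows:
        if len(fields) <= weight_idx:
            raise ParseError(f"{path}:{lineno}: expected >= {weight_idx + 1} columns")
        u, v = fields[0], fields[1]
        try:
            w = float(fields[weight_idx])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric weight {fields[weight_idx]!r}"
            ) from None
        if u == v:
            self_loops += 1
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    if self_loops:
        logger.info("read_edge_list(%s): dropped %d self-loop(s)", path, self_loops)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a weighted edge list; isolated nodes are not representable."""
    with open(path, "w") as fh:
        fh.write("#protein_a\tprotein_b\tweight\n")
        for u, v in sorted(canonical_pair(u, v) for u, v in g.edges()):
            fh.write(f"{u}\t{v}\t{g[u][v].get('weight', 1.0)!r}\n")


def read_annotations(path):
    """Read a protein->GO annotation TSV into an :class:`AnnotationTable`."""
    from .annotations import AnnotationTable

    triples = set()
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns")
        protein, go_id, aspect = fields[0], fields[1], fields[2]
        if aspect not in VALID_ASPECTS:
            if first and aspect.lower() in ("aspect", "namespace"):
                first = False
                continue
            raise ParseError(f"{path}:{lineno}: unknown aspect code {aspect!r}")
        first = False
        triples.add((protein, go_id, aspect))
    return AnnotationTable(triples)


def write_annotations(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tgo_id\taspect\n")
        for protein, go_id, aspect in sorted(table.triples):
            fh.write(f"{protein}\t{go_id}\t{aspect}\n")


def read_fasta(path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_mapping(path, direction: str = "source->target") -> IDMapTable:
    pairs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return IDMapTable(pairs, direction=direction)


def write_mapping(idmap: IDMapTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#source_id\ttarget_id\n")
        for src, dst in idmap.pairs:
            fh.write(f"{src}\t{dst}\n")


def read_domain_tables(protein_domains_path, ddi_path, domain_go_path=None) -> DomainTables:
    protein_domains: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(protein_domains_path):
        if len(fields) < 2:
            raise ParseError(f"{protein_domains_path}:{lineno}: expected 2 columns")
        protein_domains.setdefault(fields[0], set()).add(fields[1])

    ddi: set[tuple[str, str]] = set()
    for lineno, fields in _data_lines(ddi_path):
        if len(fields) < 2:
            raise ParseError(f"{ddi_path}:{lineno}: expected 2 columns")
        ddi.add(canonical_pair(fields[0], fields[1]))

    domain_go: dict[str, set[str]] = {}
    if domain_go_path is not None:
        for lineno, fields in _data_lines(domain_go_path):
            if len(fields) < 2:
                raise ParseError(f"{domain_go_path}:{lineno}: expected 2 columns")
            domain_go.setdefault(fields[0], set()).add(fields[1])

    return DomainTables(protein_domains=protein_domains, ddi=ddi, domain_go=domain_go)


def write_domain_tables(tables: DomainTables, protein_domains_path, ddi_path,
                        domain_go_path) -> None:
    with open(protein_domains_path, "w") as fh:
        fh.write("#protein_id\tdomain_id\n")
        for protein in sorted(tables.protein_domains):
            for domain in sorted(tables.protein_domains[protein]):
                fh.write(f"{protein}\t{domain}\n")
    with open(ddi_path, "w") as fh:
        fh.write("#domain_a\tdomain_b\n")
        for a, b in sorted(tables.ddi):
            fh.write(f"{a}\t{b}\n")
    with open(domain_go_path, "w") as fh:
        fh.write("#domain_id\tgo_id\n")
        for domain in sorted(tables.domain_go):
            for go_id in sorted(tables.domain_go[domain]):
                fh.write(f"{domain}\t{go_id}\n")


# ---------------------------------------------------------------------------
# Sequence-identity fallback for missing ID mappings


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity: identities / alignment columns (gaps count)."""
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def map_with_identity_fallback(
    query_id: str,
    idmap: IDMapTable,
    query_seq: SequenceRecord | None = None,
    reference_seqs: Sequence[SequenceRecord] = (),
    min_identity: float = 0.90,
) -> list[str]:
    """Map an identifier, falling back to >= ``min_identity`` sequence matches.

    Direct mapping-table hits win; otherwise every reference sequence with
    global identity at or above the threshold is returned, best first
    (identity descending, then id ascending). Returns the empty list when
    the id is unmappable (no table hit and no query sequence).
    """
    hits = idmap.lookup(query_id)
    if hits:
        return hits
    if query_seq is None:
        logger.warning("id %r unmappable: no table hit and no query sequence", query_id)
        return []
    scored = []
    for ref in reference_seqs:
        identity = global_identity(query_seq.sequence, ref.sequence)
        if identity >= min_identity:
            scored.append((identity, ref.id))
    scored.sort(key=lambda pair: (-pair[0], pair[1]))
    return [ref_id for _, ref_id in scored]
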