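"""Self-contained synthetic worlds with planted functional structure.

A world emulates the inputs the pipeline consumes in real use:

* a modular weighted PPI network (planted partition: within-module edge
  probability ``p_in`` with high Beta-distributed confidence weights,
  between-module probability ``p_out`` with low weights);
* module-coherent GO annotations — each module owns a few private GO terms
  annotated to all of its members, with a small fraction of annotations
  rewired across modules as noise;
* protein sequences whose amino-acid composition is biased toward a
  module-specific signature residue group, so physico-chemical clustering
  has real signal;
* module-private domains, within-module domain-domain interactions
  (including homotypic pairs) and domain -> GO links to the module's terms;
* a STRING-style <-> UniProt-style id mapping (one-to-many for some nodes);
* a held-out target set whose annotations are moved into a truth table
  (never present in the visible annotation table).

Everything is a deterministic function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .annotations import AnnotationTable
from .formats_io import (
    DomainTables,
    IDMapTable,
    SequenceRecord,
    canonical_pair,
    read_annotations,
    read_domain_tables,
    read_edge_list,
    read_fasta,
    read_mapping,
    write_annotations,
    write_domain_tables,
    write_edge_list,
    write_fasta,
    write_mapping,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# Signature residue groups cycled over modules; each group moves a distinct
# subset of the seven properties (aromatics -> extinction/absorbance,
# acidics -> n_neg/pI, basics -> n_pos/pI, aliphatics -> AI/GRAVY, ...).
SIGNATURE_GROUPS = (
    ("W", "Y"),
    ("D", "E"),
    ("K", "R"),
    ("I", "L", "V"),
    ("A", "G"),
    ("C", "M"),
    ("S", "T"),
    ("F", "P"),
)

ASPECT_CYCLE = ("BP", "MF", "CC")


@dataclass(frozen=True)
class WorldParams:
    """Generator parameterization; defaults define the study conditions."""

    n_modules: int = 4
    module_size: int = 25
    p_in: float = 0.3
    p_out: float = 0.02
    weight_in: tuple[float, float] = (6.0, 2.0)   # Beta params, high confidence
    weight_out: tuple[float, float] = (2.0, 6.0)  # Beta params, low confidence
    terms_per_module: int = 10
    annotation_noise: float = 0.05
    seq_length: int = 150
    composition_shift: float = 0.5
    domains_per_module: int = 3
    holdout_fraction: float = 0.2

    def validate(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if not 0 <= self.annotation_noise < 0.5:
            raise ValueError("annotation_noise must be in [0, 0.5)")
        if self.n_modules < 1 or self.module_size < 2:
            raise ValueError("parameters imply empty modules")
        if math.ceil(self.holdout_fraction * self.n_modules * self.module_size) < 1:
            raise ValueError("holdout_fraction yields no targets")


@dataclass
class SyntheticWorld:
    network: nx.Graph
    annotations: AnnotationTable
    sequences: list[SequenceRecord]
    domain_tables: DomainTables
    idmap: IDMapTable  # network (STRING-style) id -> annotation (UniProt-style) id
    truth: dict[str, frozenset[str]]
    module_of: dict[str, int]
    params: WorldParams = field(default_factory=WorldParams)
    seed: int = 0

    @property
    def targets(self) -> list[str]:
        return sorted(self.truth)


def _node_id(module: int, i: int) -> str:
    return f"S{module:02d}N{i:03d}"


def _uniprot_id(module: int, i: int) -> str:
    return f"U{module:02d}P{i:03d}"


def generate_world(params: WorldParams | None = None, seed: int = 0,
                   **overrides) -> SyntheticWorld:
    """Build a reproducible synthetic world (see module docstring)."""
    params = dataclasses.replace(params or WorldParams(), **overrides)
    params.validate()
    rng = np.random.default_rng(seed)

    modules = {
        m: [_node_id(m, i) for i in range(params.module_size)]
        for m in range(params.n_modules)
    }
    module_of = {node: m for m, members in modules.items() for node in members}
    nodes = sorted(module_of)

    # --- planted-partition network with confidence weights ----------------
    net = nx.Graph()
    net.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = module_of[u] == module_of[v]
            p = params.p_in if same else params.p_out
            if rng.random() < p:
                a, b = params.weight_in if same else params.weight_out
                net.add_edge(u, v, weight=float(np.round(rng.beta(a, b), 6)))
    # PPI snapshots carry no isolated proteins; tether any to a module mate
    for node in nodes:
        if net.degree(node) == 0:
            mates = [m for m in modules[module_of[node]] if m != node]
            mate = mates[int(rng.integers(len(mates)))]
            a, b = params.weight_in
            net.add_edge(node, mate, weight=float(np.round(rng.beta(a, b), 6)))

    # --- id mapping (one-to-one, plus one alias per module) ---------------
    pairs = []
    uniprot_of: dict[str, list[str]] = {}
    for m, members in modules.items():
        for i, node in enumerate(members):
            uid = _uniprot_id(m, i)
            pairs.append((node, uid))
            uniprot_of[node] = [uid]
        # first member also maps to an unannotated alias entry
        alias = f"U{m:02d}ALT"
        pairs.append((members[0], alias))
        uniprot_of[members[0]].append(alias)
    idmap = IDMapTable(pairs, direction="network->annotation")

    # --- module-private GO terms and annotations ---------------------------
    module_terms: dict[int, list[tuple[str, str]]] = {}
    term_counter = 1
    for m in range(params.n_modules):
        terms = []
        for j in range(params.terms_per_module):
            go_id = f"GO:{term_counter:07d}"
            terms.append((go_id, ASPECT_CYCLE[(m + j) % len(ASPECT_CYCLE)]))
            term_counter += 1
        module_terms[m] = terms

    triples = []
    all_terms = [(m, t, a) for m, terms in module_terms.items() for t, a in terms]
    for node in nodes:
        m = module_of[node]
        uid = uniprot_of[node][0]
        for go_id, aspect in module_terms[m]:
            if rng.random() < params.annotation_noise:
                # rewire across modules: swap in a term owned by another module
                others = [(t, a) for mm, t, a in all_terms if mm != m]
                go_id, aspect = others[int(rng.integers(len(others)))]
            triples.append((uid, go_id, aspect))
    annotations = AnnotationTable(triples)

    # --- sequences with module-biased composition --------------------------
    letters = np.array(list(AA))
    sequences = []
    for node in nodes:
        m = module_of[node]
        signature = SIGNATURE_GROUPS[m % len(SIGNATURE_GROUPS)]
        alpha = np.ones(len(AA))
        for aa in signature:
            alpha[AA.index(aa)] += params.composition_shift * 20.0 / len(signature)
        comp = rng.dirichlet(alpha)
        seq = "".join(rng.choice(letters, size=params.seq_length, p=comp))
        sequences.append(SequenceRecord(node, seq))

    # --- module-private domains, DDIs, domain->GO --------------------------
    protein_domains: dict[str, set[str]] = {}
    ddi: set[tuple[str, str]] = set()
    domain_go: dict[str, set[str]] = {}
    for m, members in modules.items():
        domains = [f"PF{m:02d}{j:03d}" for j in range(params.domains_per_module)]
        for i, a in enumerate(domains):
            ddi.add(canonical_pair(a, a))
            for b in domains[i + 1:]:
                ddi.add(canonical_pair(a, b))
            domain_go[a] = {t for t, _ in module_terms[m]}
        for node in members:
            uid = uniprot_of[node][0]
            keep = {d for d in domains if rng.random() < 0.7}
            if not keep:
                keep = {domains[int(rng.integers(len(domains)))]}
            protein_domains[uid] = keep
            # the alias id (when present) carries the same domains
            for extra in uniprot_of[node][1:]:
                protein_domains[extra] = set(keep)
    domain_tables = DomainTables(
        protein_domains=protein_domains, ddi=ddi, domain_go=domain_go
    )

    # --- hold out targets ---------------------------------------------------
    n_targets = math.ceil(params.holdout_fraction * len(nodes))
    target_nodes = sorted(str(n) for n in rng.choice(nodes, size=n_targets, replace=False))
    truth: dict[str, frozenset[str]] = {}
    held_uids = set()
    for node in target_nodes:
        uids = uniprot_of[node]
        terms = frozenset(
            t for uid in uids for t in annotations.terms_for(uid)
        )
        truth[node] = terms
        held_uids.update(uids)
    annotations = annotations.without_proteins(held_uids)

    return SyntheticWorld(
        network=net,
        annotations=annotations,
        sequences=sequences,
        domain_tables=domain_tables,
        idmap=idmap,
        truth=truth,
        module_of=module_of,
        params=params,
        seed=seed,
    )


def full_annotation_table(world: SyntheticWorld) -> AnnotationTable:
    """The world's visible annotations plus the held-out truth, as one table.

    This is the leave-one-out evaluation universe: when predicting target T,
    every protein's annotations except T's own are legitimately visible.
    Truth terms are re-attached to each target's primary annotation-namespace
    id; a truth term whose aspect cannot be recovered from the visible table
    is skipped (cannot happen while every term retains a non-target carrier).
    """
    aspect_of = world.annotations.term_aspects()
    triples = set(world.annotations.triples)
    for target, terms in world.truth.items():
        ids = world.idmap.lookup(target) or [target]
        for term in terms:
            aspect = aspect_of.get(term)
            if aspect is not None:
                triples.add((ids[0], term, aspect))
    return AnnotationTable(triples)


def shuffle_annotations(table: AnnotationTable, seed: int = 0) -> AnnotationTable:
    """Null model: reassign the annotation table's protein column at random.

    Term multiplicities are preserved; the protein <-> term association is
    destroyed, so planted-term recovery should collapse to chance.
    """
    rng = np.random.default_rng(seed)
    triples = sorted(table.triples)
    proteins = [p for p, _, _ in triples]
    perm = rng.permutation(len(proteins))
    shuffled = [
        (proteins[perm[i]], t, a) for i, (_, t, a) in enumerate(triples)
    ]
    return AnnotationTable(shuffled)


def null_model(world: SyntheticWorld, seed: int = 0) -> tuple[AnnotationTable, DomainTables]:
    """Label-shuffled null for the whole world.

    Permutes the protein column of the full annotation table (visible +
    held-out truth) and rederives the domain -> GO table from the shuffled
    labels (a domain's terms become the shuffled terms of its carrier
    proteins, mirroring how domain-function links are curated from protein
    annotations in the first place). All three predictors then see only
    randomized function knowledge; the real truth is kept for scoring.
    """
    shuffled = shuffle_annotations(full_annotation_table(world), seed=seed)
    domain_go: dict[str, set[str]] = {}
    for protein, domains in world.domain_tables.protein_domains.items():
        terms = shuffled.terms_for(protein)
        for domain in domains:
            domain_go.setdefault(domain, set()).update(terms)
    tables = DomainTables(
        protein_domains={p: set(d) for p, d in world.domain_tables.protein_domains.items()},
        ddi=set(world.domain_tables.ddi),
        domain_go=domain_go,
    )
    return shuffled, tables


# ---------------------------------------------------------------------------
# Disk round trip

FILES = {
    "network": "network.tsv",
    "annotations": "annotations.tsv",
    "sequences": "sequences.fasta",
    "protein_domains": "protein_domains.tsv",
    "ddi": "ddi.tsv",
    "domain_go": "domain_go.tsv",
    "idmap": "idmap.tsv",
    "truth": "truth.tsv",
    "params": "params.json",
}


def write_world(world: SyntheticWorld, directory) -> None:
    """Emit every on-disk artifact the pipeline readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edge_list(world.network, directory / FILES["network"])
    write_annotations(world.annotations, directory / FILES["annotations"])
    write_fasta(world.sequences, directory / FILES["sequences"])
    write_domain_tables(
        world.domain_tables,
        directory / FILES["protein_domains"],
        directory / FILES["ddi"],
        directory / FILES["domain_go"],
    )
    write_mapping(world.idmap, directory / FILES["idmap"])
    with open(directory / FILES["truth"], "w") as fh:
        fh.write("#target_id\tgo_id\n")
        for target in sorted(world.truth):
            for term in sorted(world.truth[target]):
                fh.write(f"{target}\t{term}\n")
    with open(directory / FILES["params"], "w") as fh:
        json.dump(
            {
                "seed": world.seed,
                "params": dataclasses.asdict(world.params),
                "module_of": world.module_of,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_world(directory) -> SyntheticWorld:
    """Load a world written by :func:`write_world`."""
    directory = Path(directory)
    with open(directory / FILES["params"]) as fh:
        meta = json.load(fh)
    truth: dict[str, frozenset[str]] = {}
    tmp: dict[str, set[str]] = {}
    with open(directory / FILES["truth"]) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            target, term = line.rstrip("\n").split("\t")
            tmp.setdefault(target, set()).add(term)
    truth = {t: frozenset(terms) for t, terms in tmp.items()}
    return SyntheticWorld(
        network=read_edge_list(directory / FILES["network"]),
        annotations=read_annotations(directory / FILES["annotations"]),
        sequences=read_fasta(directory / FILES["sequences"]),
        domain_tables=read_domain_tables(
            directory / FILES["protein_domains"],
            directory / FILES["ddi"],
            directory / FILES["domain_go"],
        ),
        idmap=read_mapping(directory / FILES["idmap"], direction="network->annotation"),
        truth=truth,
        module_of=meta["module_of"],
        params=WorldParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["params"].items()
        }),
        seed=meta["seed"],
    )
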