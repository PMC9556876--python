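# Methods

## The prediction model

`pfpgo` treats protein function prediction as label transfer over a locally
refined interaction neighborhood, merged across three independent evidence
channels. The underlying assumptions are the classical ones of
network-based function prediction: interacting proteins tend to share
function (guilt by association), functional modules are densely
interconnected and carry coherent annotation, domains are the structural
units that mediate function, and sequence composition reflects the
physico-chemical regime a protein operates in. None of the channels uses
sequence alignment or ontology structure; GO terms are flat labels
throughout (no true-path propagation — an optional pre-closure hook exists
but is off by default, since the method ranks terms exactly as annotated).

### Neighborhood refinement

For a target t, the working graph is the subgraph induced on all proteins
within two hops of t (level-1 and level-2 neighbors, with *all* induced
edges, including level-2↔level-2). Refinement has two stages.

**Pruning.** Every non-target node is classified on the original
neighborhood, in priority order: *bridge* — an articulation vertex, whose
removal disconnects the subgraph; else *fjord* — degree ≥ 2 with no triangle
through it (a pure connector with zero local clustering); else *shore* — a
leaf. All labeled nodes are removed simultaneously, so the result does not
depend on removal order. The target is never removed. These three
categories operationalize the intuition that nodes which merely *connect*
regions, rather than participate in them, contribute noise to
neighborhood-based transfer.

**Double filtering.** Two edge passes with the adaptive threshold
`T(values) = α + k·σ·(1 − 1/(1+σ²))` (α mean, σ *population* standard
deviation, default k = 3). Pass 1 computes the edge clustering coefficient
ECC(u,v) = |N(u)∩N(v)| / min(deg u − 1, deg v − 1) for every edge (ECC = 0
when an endpoint has degree 1, so leaf edges never look cohesive) and drops
edges with ECC strictly below T(all ECCs). Pass 2 drops surviving edges with
weight strictly below T(surviving weights). Strict `<` makes a zero-variance
pass a no-op rather than a wipe-out: T collapses to the mean when σ = 0.
ECC is not recomputed between passes. Nodes left isolated are dropped,
except the target. Note the threshold sits just above the mean for small σ
(the correction term is ≈ k·σ³), so each pass removes roughly the
below-average half of its value distribution — the filter is deliberately
aggressive, keeping only the most reliable, module-embedded edges.

### The three predictors

**Sequence.** Seven composition-based properties per protein: molar
extinction coefficient at 280 nm (Gill–von Hippel, 5500·nW + 1490·nY +
125·⌊nC/2⌋, oxidized-cystine convention), absorbance (E/MW), counts of
negative (D, E) and positive (R, K; His excluded, ProtParam convention)
residues, Ikai aliphatic index (X_A + 2.9·X_V + 3.9·(X_I + X_L), mole
percent), isoelectric point over molecular weight in kDa, and GRAVY (mean
Kyte–Doolittle hydropathy). pI is solved by bisection on the
Henderson–Hasselbalch net-charge curve with a pinned pKa table (termini
2.34 / 9.60; side chains D 3.65, E 4.25, H 6.00, C 8.18, Y 10.07, K 10.53,
R 12.48) to 1e-4 pH units; MW uses Expasy average residue masses plus one
water. All constants live in `pfpgo/constants.py`.

The raw properties span ~6 orders of magnitude, so all distances use
vectors z-scored against the refined neighborhood (components with zero
variance map to 0). Clustering is greedy and graph-aware: the unassigned
node of highest degree (ties by id) seeds a cluster and absorbs its
unassigned direct neighbors within a Euclidean distance threshold (default:
the adaptive threshold over all pairwise member distances — the method's
single thresholding device reused). The target is assigned to the cluster
with the nearest centroid and inherits the GO terms of the one nearest
member, each scored 1/(1+distance). Distances use the full 7-vector; a
scalar mode (mean of z-scored components) exists behind a flag but
collapses information.

**Domain.** Neighborhood proteins are mapped — through a chain of
one-to-many id mappings, all hits propagated — to their domains. For every
refined edge (u,v), domain pairs (a ∈ dom(u), b ∈ dom(v)) present in the
DDI table are *validated*. Every (protein, domain) instance whose domain
participates in a validated pair contributes one occurrence of each of the
domain's GO terms; terms are ranked by occurrence count (ties by term id)
and scored count/max count, top 10 returned. Counting per protein-domain
instance rather than per edge pair keeps the ranking proportional to how
widely a domain (and hence its functions) is carried in the neighborhood,
instead of re-introducing the raw edge-density signal the filter just
removed. When a domain has no direct GO link, the annotations of the
proteins carrying it are used as a fallback.

**Topology.** Candidate terms are those annotated to refined neighbors (the
target's own annotations are excluded — no leakage). For each term, with x
annotated neighbors carrying it among n annotated neighbors, K carriers
among N annotated background proteins (default background: all annotated
proteins of the input network), the one-sided Fisher exact p-value is the
hypergeometric upper tail P(X ≥ x), computed via `scipy.stats.hypergeom.sf`.
Terms are ranked by p ascending (ties: larger x, then term id), scored
1 − p, top 10 returned; an optional α post-filter and Benjamini–Hochberg
correction exist behind flags but are off by default since the ranking uses
raw p. Because the predictor needs only a node→term map, it applies to any
gene-level association network.

### Consensus and evaluation

A term reaches star level n when ≥ n predictors propose it; 3-star
(unanimous) is the default and most precise, 1-star is the union. The
combined score is the mean of contributing scores; the support count is
carried as categorical confidence. A predictor with no output for a target
simply contributes nothing (3-star then being unreachable is logged).

Evaluation is leave-one-out: predicting target t uses the full annotation
table minus t's own entries; t's annotations serve only as truth. Per
target, P = |pred∩truth|/|pred| (0 for empty predictions),
R = |pred∩truth|/|truth|, F = 2PR/(P+R); targets with empty truth are
excluded (logged). Aggregation is the unweighted (macro) mean; micro
averaging is available behind a flag. Fmax scans thresholds 0.00–1.00 in
steps of 0.01, averages precision over targets with ≥ 1 prediction at the
threshold and recall over all targets (CAFA convention), and takes the best
harmonic mean.

### Identifier mapping

Mappings are one-to-many in both directions; every hit propagates. When an
id is absent from the table, global pairwise alignment (match 1, mismatch 0,
linear gap −1; identity = identical columns / alignment columns, gaps in the
denominator) against a reference set stands in: all references with
identity ≥ 0.90 (inclusive) are returned, best first. An id with no table
hit and no sequence is reported unmappable, not an error.

## The synthetic world

`generate_world(params, seed)` builds a complete input set with planted
truth; everything derives from one seeded generator, so a (params, seed)
pair reproduces the world byte-for-byte. Defaults (the standard study
conditions):

| parameter | default | meaning |
|---|---|---|
| n_modules × module_size | 4 × 25 | planted functional modules |
| p_in / p_out | 0.3 / 0.02 | within/between-module edge probability |
| weight_in / weight_out | Beta(6,2) / Beta(2,6) | edge confidence (mean ≈ 0.75 / 0.25) |
| terms_per_module | 10 | private GO terms per module, annotated to every member |
| annotation_noise | 0.05 | fraction of annotations rewired to another module's term |
| seq_length | 150 | residues per protein |
| composition_shift | 0.5 | Dirichlet bias toward the module's signature residues |
| domains_per_module | 3 | private domains, all within-module DDIs (incl. homotypic) |
| holdout_fraction | 0.2 | nodes whose annotations move to the truth table |

Design notes. Ten terms per module matches typical per-protein GO
annotation density and — together with 4 modules — yields a 40-term
vocabulary, large enough that chance agreement of three top-10 lists is
negligible; module-specific signature residue groups (aromatic, acidic,
basic, aliphatic, …) each move a distinct subset of the seven properties,
so the sequence channel has real, recoverable signal; the beta weight split
mimics STRING's separation between high-confidence functional edges and
background noise; isolated nodes are tethered to a module mate because
interaction snapshots carry no isolated proteins. Node ids and annotation
ids live in two namespaces joined by a one-to-many mapping (one alias per
module) so the id-mapping layer is genuinely exercised.

The **label-shuffled null** (`null_model`) permutes the protein column of
the full annotation table *and* rederives domain→GO links from the shuffled
labels — domain–function links are annotation-derived knowledge, so a
faithful null randomizes them too. Truth is kept real for scoring.

What the world does **not** emulate: scale-free degree distributions, hub
proteins, realistic protein sequences (composition only, no motifs),
overlapping modules, incomplete or biased annotation coverage, and
real-database identifier messiness. Passing the recovery checks therefore
demonstrates that the pipeline's machinery recovers planted modular signal
through all of its stages — not that it attains any particular accuracy on
real proteome-scale data.

## Numerical and procedural choices

* Population (not sample) standard deviation in the adaptive threshold;
  strict `<` for all removals/admissions.
* All ties broken deterministically by id or term id; no iteration-order
  dependence anywhere.
* Edge-list reading collapses duplicate/reversed rows keeping the maximum
  weight and drops self-loops (logged); scores are stored exactly as read
  (STRING 0–999 integers are not rescaled).
* Target sampling uses `ceil(fraction·n)` without replacement from a sorted
  candidate pool under `numpy.random.default_rng(seed)`; the post-hoc
  deduplication pass is a logged no-op kept for parity with
  with-replacement variants.
* pI bisection is guarded at 100 iterations (the net-charge curve is
  strictly monotone, so convergence to 1e-4 needs ~18).
* The degenerate σ=0 threshold, empty prediction sets, unmappable ids, and
  targets with no annotated neighbors all degrade to explicit empty results
  with warnings, never exceptions.

## Problem sizes

The default world (100 proteins, ~400 edges, 20 targets) runs the full
pipeline in ~2 s on one core; the test suite, including exhaustive
small-graph ECC checks, exhaustive hypergeometric enumeration to N = 12 and
a 2 000-draw null calibration, completes in well under a minute. These
sizes were chosen so every oracle can be exhaustive or near-exhaustive
while the planted signal remains comfortably recoverable.

## Known limitations

* A target whose two-hop neighborhood captures a dense chunk of a foreign
  module through chance cross edges can mislead all three channels at once;
  at the default scale this affects roughly 1–3 of 20 targets and is the
  dominant error mode (macro 3-star F ≈ 0.75–0.85 across world seeds).
* The double filter's near-mean threshold halves the edge set twice; for
  low-degree targets this can strip every direct edge, leaving prediction
  to rest entirely on the surviving (possibly disconnected) module core.
* The sequence channel transfers annotations from a single nearest member,
  so its recall is capped by that member's annotation completeness.
* Flat-label evaluation understates performance relative to
  ontology-aware metrics: a predicted parent of a true term counts as a
  miss.
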