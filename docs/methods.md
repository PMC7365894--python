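# Methods

## Scope and data model

The package analyses component–target (C-T) networks of multi-herb
prescriptions. Its inputs are tabular: component property tables
(id, name, formula, herb, MW, logP, H-bond donors/acceptors, rotatable
bonds, OB%, DL), component→target edge lists, optional target–target
interaction (TTI) edge lists, disease gene lists with literature-evidence
counts, and GMT pathway collections. Target prediction, pathway-database
retrieval and visualization are deliberately out of scope: edges,
evidence counts and gene sets are inputs.

Component identity for all cross-formula set operations is the
case-folded, whitespace-collapsed **name**, because the same molecule
recurs under different formula-local ids and herbs. Gene symbols are
upper-cased at ingest; no alias resolution is attempted (determinism
without an external database). Component ids and gene symbols must not
collide; the network container enforces disjoint namespaces and forbids
self-loops and component–component edges.

## ADME screen

Seven rules, evaluated as a strict conjunction: MW ≤ 500 Da,
HDON ≤ 5, HACC ≤ 10, −2 ≤ logP ≤ 5, RBN ≤ 10, OB ≥ 30%, DL ≥ 0.14.
Bounds are **inclusive** by default: the packaged post-screening table
contains components sitting exactly on the limits (quercetin HDON = 5,
Lactiflorin and Bifendate HACC = 10, DMEP RBN = 10, 6-shogaol DL = 0.14),
so strict comparisons would reject rows that the published screen
retained. `inclusive=False` (CLI `--strict-bounds`) reproduces the
literal strict-inequality reading instead. A missing or NaN property
rejects the component with reason `missing`; it is never passed silently.

Disease genes are kept when their evidence count is **strictly greater**
than the threshold (default 5, configurable): "more than five reports"
is read as > 5.

## Network construction and statistics

The C-T graph is undirected and unweighted by default; positive edge
weights are accepted and propagate into the random-walk model. Mean
degrees are reported to two decimals in two conventions — over C-T edges
only, and over all edges including TTI — because the two differ as soon
as interaction edges are merged and published degree summaries do not
always state which convention they use. Isolated components are retained
in the network (flagged), but dropped with a warning before the walk,
which cannot visit degree-0 nodes.

## Map equation

For an undirected, possibly weighted network, the stationary visit rate
of node α is p_α = w_α / 2W (weighted degree over twice total edge
weight). For a partition M into m modules the two-level map equation is

    L(M) = q↶ H(Q) + Σᵢ pᵢ↻ H(Pⁱ)

where qᵢ↷ = qᵢ↶ = (boundary weight of module i) / 2W, q↶ = Σᵢ qᵢ↶,
pᵢ↻ = qᵢ↷ + Σ_{α∈i} p_α, H(Q) is the entropy of {qᵢ↶/q↶} and H(Pⁱ) the
entropy of {qᵢ↷/pᵢ↻} ∪ {p_α/pᵢ↻}. All logarithms are base 2 and
0·log 0 := 0, so modules with no boundary contribute no exit term and the
one-module partition has L = −Σ p_α log₂ p_α exactly. (One printed source
formula normalizes H(Q) by qᵢ↶ itself; that is a typo for q↶ — Q is
explicitly the normalized distribution.)

The optimizer maintains per-module aggregates (Σp, q) and scores node
moves through the equivalent closed form
L = g(Q) − 2Σᵢ g(qᵢ) + Σᵢ g(qᵢ + Sᵢ) − Σ_α g(p_α), g(x) = x log₂ x,
so a move costs O(deg). Each trial starts from singletons, runs greedy
sweeps (every node to the neighboring module that most lowers L, until a
full sweep makes no move), then merge-and-fine-tune passes: every
connected module pair is tentatively merged and re-swept, and the merge
is kept if the combined effect lowers L. The pair step matters: pure
node-moves plus pure merges stall on, e.g., a six-node path whose
three-pair partition is locally stable but whose two-triple partition is
globally better. Trials (default 20) use shuffled node orders from a
seeded generator; the minimum-L labeling wins. Ties everywhere break
toward the smallest module label / node id; the improvement tolerance is
1e−12 bits. Disconnected inputs are optimized per connected component
and module ids renumbered globally.

An exhaustive enumerator over all set partitions (guarded at n ≤ 10)
serves as the optimality oracle; the floating-point codelength is also
checked against an exact-rational evaluation of the printed formulas
(rates as `fractions.Fraction`, logs applied last) to 1e−9.

## Module significance

Published per-motif p-values come without a stated procedure, so the
package defines one: the statistic of a module is the total edge weight
internal to its fixed node set; the null model preserves every node's
degree by double edge swaps (10 × |E| attempted swaps per replicate,
weights travelling with edges; rejected proposals — self-loops or
parallel edges — leave the state unchanged, keeping the chain symmetric).
The empirical p-value is (1 + #{null ≥ observed}) / (n_null + 1),
BH-adjusted across modules; modules with adjusted p < α (default 0.05)
form the KNMS set.

Because a single swap chain only approximately mixes, drawing every null
directly from the observed graph would make the observed statistic
"central" among its own nulls and distort p-values. The package instead
uses the parallel Besag–Clifford construction: the observed graph is
first rewired into a hub state and every null chain restarts from that
hub. Reversibility then makes the observed graph and the nulls exactly
exchangeable — p-values are uniform under the null regardless of mixing,
which the calibration test verifies (KS uniformity over 200
configuration-model replicates at n_null = 99). One caveat is discrete
statistics: with unweighted edges the internal-edge count ties with its
null draws at an appreciable rate, and the ≥ counting rule then makes
p-values conservative (stochastically larger than uniform) by about half
the tie probability. This is the standard behaviour of unsmoothed
empirical p-values; the calibration experiment therefore uses continuous
edge weights, for which the statistic is tie-free. With 199 nulls the
smallest attainable p is 1/200, which is what a strictly maximal module
(e.g. a planted clique) attains.

## Scoring and validation

*Contribution coefficient.* R = (d_c − d_min)/(d_max − d_min) over the
**full network's component degrees** (targets excluded);
CC(module) = 100 × Σ_module R / Σ_network R. When every component has the
same degree the formula is 0/0; all R are then set to 1, which keeps CC
defined, additive over disjoint modules, and equal to 100 for the full
set. The degenerate rule matters only for near-regular networks.

*Pathogenic-gene coverage.* 100 × |KNMS ∩ disease| / |C-T ∩ disease|,
reported with counts; undefined (flagged, not NaN) when the network
contains no disease genes.

*Pathway enrichment.* One-sided hypergeometric upper tail
P(X ≥ k | N, K, n) per pathway. The background defaults to the union of
all pathway genes and is configurable to the C-T target universe; the
cutoff (default 0.05) applies to raw p-values by default, with BH
adjustment available. Published analyses rarely state either choice, so
both are explicit parameters rather than inferred conventions. Pathway
coverage is 100 × |subset ∩ reference| / |reference|.

*Rounding.* Percentages are rounded to one decimal, means to two,
half-to-even, and only at reporting; internal arithmetic is unrounded.
(One consequence: a mean of exactly 31.325 reports as 31.32, where
half-up conventions print 31.33.)

*Overlap accounting.* "Common" components are those in every formula.
A formula's "unique" count is its set size minus the common core — the
convention under which the three studied formulas decompose as
124 = 31 + 93, 120 = 31 + 89 and 48 = 31 + 17. The stricter
found-in-no-other-formula count is reported separately as "exclusive",
and all 2^k − 1 Venn regions are emitted.

## Synthetic data

The planted-network generator emulates the modular bipartite structure
the detector is meant to find: components and targets split evenly into
blocks, C-T pairs linked with p_in within a block and p_out across
(defaults 40 components, 80 targets, 4 modules, p_in = 0.4, p_out = 0.02
— component degrees ≈ 9 and target degrees ≈ 4–5, comparable to the
published networks' density, with unambiguous planted structure). Draws
are regenerated until connected (p_out = 0 makes cross-block connection
impossible; the draw is then returned as-is with a warning). Pathway
collections are sampled with a `signal` parameter: an anchored pathway
takes 80% of its genes from one block, `signal = 0` makes membership
independent of structure. Disease genes get evidence counts uniform on
1..20. All generators are pure functions of their seeds.

What the synthetic inputs do **not** emulate: the score distributions of
target-prediction tools, degree heterogeneity of real C-T networks
(real component degrees are heavy-tailed; planted blocks are
near-homogeneous), overlapping pathway hierarchies, and literature
citation dynamics. Tests passing on these fixtures therefore validate the
algorithmic machinery — exact codelength, optimizer optimality at small
n, calibrated significance, coverage arithmetic — not that real networks
for the three formulas would yield the published motif counts. Those
depend on unreleased edge sets and a pathway-database snapshot, and the
package makes no attempt to reproduce them (the published per-formula
motif counts, cumulative CC values and C-T-level pathway coverages are
treated as non-reproducible at desk scale).

## Problem sizes and determinism

Default verification sizes: 100 random connected graphs (n ≤ 8) for the
enumeration-oracle suite, 60 random graphs for the rational-oracle
codelength suite, 20 planted draws for recovery (mean adjusted Rand
index ≥ 0.9), and 200 configuration-model replicates at n_null = 99 for
calibration. Every stochastic step takes an explicit seed; sub-seeds are
drawn from a single `numpy` generator, so identical (inputs, config,
seed) reproduce byte-identical outputs. The pipeline is single-threaded.

## Known limitations

- Two-level map equation only: no hierarchical modules, no overlapping
  membership, no teleportation; directed walks are out of scope.
- The rewiring null conditions on the degree sequence only; it does not
  preserve bipartite block structure beyond degrees.
- Empirical p-values are conservative in the presence of statistic ties
  (see above); n_null bounds the smallest attainable p at 1/(n_null+1).
- Enrichment assumes a well-defined gene universe; with tiny backgrounds
  the hypergeometric tail is lumpy and the 0.05 cutoff coarse.
- No chemical-structure computation: property values are trusted as
  given, and name normalization does not resolve chemical synonyms.
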