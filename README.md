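# knms

Network-pharmacology analysis of multi-herb prescriptions: from screened
chemical components to statistically significant gene network motifs.

Traditional multi-herb formulas act through many components hitting many
protein targets at once. Given per-component ADME property tables and
component→target edge lists, this package (1) screens for orally active,
drug-like components, (2) builds the bipartite component–target (C-T)
network, (3) decomposes it into **key gene network motifs with
significance (KNMS)** — modules found by minimizing the map equation and
tested against a degree-preserving null — and (4) validates the motif set
against the full network by pathogenic-gene coverage, KEGG-style pathway
coverage, and cumulative contribution of its components. A cross-formula
overlap analysis quantifies which components different prescriptions for
the same disease share.

It ships the published post-screening property table of three rheumatoid
arthritis prescriptions (DSD, GFD, HGWD; 292 rows) as a packaged fixture,
plus seeded synthetic generators for every other input, so the entire
pipeline runs and is tested without any downloads.

## The model

**ADME screen.** A component is active iff it satisfies all seven rules
(inclusive bounds): MW ≤ 500 Da, H-bond donors ≤ 5, acceptors ≤ 10,
−2 ≤ logP ≤ 5, rotatable bonds ≤ 10, oral bioavailability OB ≥ 30%, and
drug-likeness DL ≥ 0.14.

**Map equation.** A random walker on the undirected network visits node α
with stationary probability p_α = w_α / 2W. For a partition M of the
network into m modules, the expected per-step description length under a
two-level (index + module codebook) coding is

```
L(M) = q↶ H(Q) + Σᵢ pᵢ↻ H(Pⁱ)
```

with qᵢ↶ = qᵢ↷ the rate of entering/exiting module i (half its boundary
weight over W), q↶ = Σᵢ qᵢ↶, pᵢ↻ = qᵢ↷ + Σ_{α∈i} p_α, and H(·) the
entropy (bits) of the normalized rate distributions. Lower L means the
partition better compresses the walk; minimizing L over partitions yields
the motifs. The optimizer is a seeded greedy node-move heuristic with
merge-and-fine-tune passes and restarts, exactly verified against
exhaustive enumeration on small graphs.

**Significance.** Each module's internal edge weight is compared with
degree-preserving double-edge-swap rewirings (exchangeable by a
Besag–Clifford hub construction); empirical p-values are BH-adjusted and
modules with q < 0.05 form the KNMS set.

**Scoring.** Component importance is min–max-normalized degree
R = (d − d_min)/(d_max − d_min); a module's contribution coefficient is
CC = 100 × Σ_module R / Σ_network R, so CC is additive and the full
network scores 100. Pathway enrichment is the one-sided hypergeometric
upper tail; coverages are plain percentage arithmetic.

## Worked example

```python
from knms import adme_filter, common_unique, component_name_sets
from knms.fixtures import packaged_table2, gen_planted_network, PlantedNetworkSpec
from knms.motifs import detect_motifs
from knms.scoring import contribution_coefficient, round1

table = packaged_table2()
active, rejected = adme_filter(table)
print(f"active components: {len(active)} (rejected: {len(rejected)})")

result = common_unique(component_name_sets(active))
print(f"common to all formulas: {result.common}")
print(f"unique per formula: {result.unique}")

net, truth = gen_planted_network(PlantedNetworkSpec(seed=0))
res = detect_motifs(net, trials=8, n_null=199, seed=0)
print(f"codelength: {res.terms.codelength:.4f} bits in {res.terms.m} modules")
print(f"significant modules (q < 0.05): {sorted(res.knms)}")
degrees = {c: net.graph.degree(c) for c in net.component_nodes}
for m in sorted(res.knms):
    comps = [n for n in res.partition.members[m] if n in degrees]
    cc = contribution_coefficient(comps, degrees)
    print(f"  module {m}: {len(res.partition.members[m])} nodes, "
          f"CC = {round1(cc)}%, q = {res.q_values[m]:.4f}")
```

prints

```
active components: 292 (rejected: 0)
common to all formulas: 31
unique per formula: {'DSD': 93, 'GFD': 89, 'HGWD': 17}
codelength: 5.6171 bits in 4 modules
significant modules (q < 0.05): [1, 2, 3, 4]
  module 1: 31 nodes, CC = 23.3%, q = 0.0050
  module 2: 30 nodes, CC = 22.1%, q = 0.0050
  module 3: 29 nodes, CC = 30.5%, q = 0.0050
  module 4: 30 nodes, CC = 24.1%, q = 0.0050
```

All 292 packaged components clear the screen (the table is the
post-screening set: 124 DSD + 120 GFD + 48 HGWD); 31 molecules are shared
by all three formulas while 93/89/17 are not. On a planted four-module
network the detector recovers all four blocks, each significant at
q = 1/200 (the smallest value 199 null draws allow), and their CC values
sum to 100% because together they contain every component.

The same steps are available as a CLI (`knms screen / overlap / build /
detect / score / validate / simulate / run-all`); `knms run-all --config
cfg.yaml` executes the whole pipeline and writes a single JSON report.

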