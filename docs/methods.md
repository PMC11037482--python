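# Methods

## Model and procedure

The prioritizer ranks digenic variant combinations by fusing two
independent lines of evidence.

**Candidate generation.** Variants from a single-sample VCF are joined to a
sidecar annotation TSV (gene, consequence class, MAF, exon-edge distance) and
filtered on the profile of variants reported as causal in curated oligogenic
cases: a variant is removed iff MAF > 3.5%, or it is intronic, or it is
synonymous and lies more than 195 nt from the nearest exon edge. A variant
with no MAF value is kept (absence of frequency evidence is not evidence of
commonness); likewise a synonymous variant with no distance value. Candidates
are then all combinations over unordered gene pairs with 1–2 variants per
gene; a gene with *n* kept variants contributes f(*n*) = *n* + *n*(*n*−1)/2
subsets, and the total candidate count is Σ f(*n_A*)·f(*n_B*) over pairs.
A homozygous genotype is one variant entity (zygosity is a scorer feature,
not a combinatorial multiplier); hemizygous calls are treated as homozygous.

**Pathogenicity (PS).** Each combination gets a score in [0, 1] from a
scorer satisfying a small deterministic contract. The production scorer is
an externally trained gene-pair classifier and is deliberately outside this
package; bundled are a lookup-table adapter for precomputed scores (strict
or lenient on missing ids) and a platform-stable SHA-256 surrogate with
per-gene-pair overrides used by the synthetic benchmark. For workflows that
retrain a scorer, fold assignment grouped by gene pair is provided: groups
are seeded-shuffled and greedily placed into the smallest fold, so no gene
pair ever spans folds and fold sizes differ by at most the largest group.
Per-fold retraining itself is the caller's responsibility.

**Disease relevance (DS).** The patient's HPO terms and/or panel genes are
resolved against a multiplex-heterogeneous knowledge graph (node ids
namespaced by type) and seeded uniformly: p⁰ has mass 1/|seeds| on each
resolved seed. HPO and gene seeds share one uniform distribution over the
union; literal terms only, with no ontology-ancestor expansion. The walk

p⁽ᵗ⁺¹⁾ = (1 − r)·W·p⁽ᵗ⁾ + r·p⁰

is iterated to stationarity, where W is the column-normalized adjacency of
the layer-flattened, unweighted, undirected simple graph (an edge exists iff
at least one layer connects the pair). The oligogenic-interaction node type
is removed before propagation — it encodes the very associations being
predicted. DS of a pair is the mean of the two genes' stationary scores.

**Fusion and ranking.** PS and DS are min–max scaled within the exome and
averaged (operators `product`, `min`, `max` are selectable alternatives).
Combinations are ranked by decreasing fused score.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` (restart probability) | 0.3 | fraction of each step teleporting to seeds; higher keeps the walk local to seeds |
| `tol` | 1e-9 (L1) | convergence threshold on successive iterates |
| `max_iter` | 1000 | iteration cap; convergence is geometric at rate (1−r), so ~40–70 iterations suffice at r = 0.3 |
| `maf_max` | 0.035 | MAF removal threshold |
| `synonymous_max_exon_distance` | 195 nt | synonymous-variant distance cutoff |
| fusion operator | mean | aggregation of the scaled scores |
| PS threshold | off | optional pre-ranking cutoff; all combinations are ranked by default |

## Numerical and design choices

* **Layer flattening.** The propagation equation is written for a single W,
  so layers are flattened to a union-of-edges simple graph rather than a
  supra-adjacency walk with inter-layer jump probabilities; the layer field
  is retained on edge records for provenance only. Per-layer normalization
  before aggregation would be an alternative reading; it is not implemented
  and defaults do not depend on it.
* **Isolated nodes** are dropped from the walk index (keeping W strictly
  column-stochastic without teleportation corrections) and score 0; genes
  absent from the index contribute 0 to DS rather than erroring, logged once
  per gene.
* **Degenerate min–max** (all values equal) maps to 0.5, so a constant
  signal neither dominates nor vanishes in the mean.
* **Ties** are broken deterministically in the ranking (higher scaled PS,
  then lexicographic combination id), and evaluated conservatively: the
  truth's reported rank under fused-score ties is the *worst* position among
  tied records.
* **Filter accounting.** A variant violating several rules is counted once,
  under the first rule in the order MAF → intronic → synonymous-distance.
* **Seed resolution** accepts bare symbols/terms (namespaced automatically)
  or ids already present verbatim in the graph index; unresolved ids warn,
  and only a fully unresolved seed set is an error.
* **Determinism.** All randomness flows through explicit integer seeds
  (numpy `default_rng` and a seeded SHA-256 surrogate); identical
  configurations produce byte-identical ranking files.

## The synthetic benchmark

The fixture generator emulates the *shape* of a spike-in benchmark, not its
biology: 2-contig artificial coordinates, independent variants (no linkage
disequilibrium or ancestry structure), uniform gene assignment, log-uniform
MAFs, and Erdős–Rényi background layers in the graph. Planted structure is
explicit: the two truth genes are connected to every seed node, and the
truth pair's pathogenicity override (0.99) is near the top of the surrogate's
range.

Study conditions, chosen once: a graph of 60 genes, 30 HPO terms and 10
disease nodes at background edge probability 0.05; 3 HPO seeds plus a
2-gene panel; 80 template variants per exome over 25 genes, yielding roughly
2 000–5 000 candidate combinations per exome after filtering. Two details
are forced by the evaluation semantics rather than tuned:

* template genes are disjoint from the truth genes — the pathogenicity
  override applies to the whole gene pair, so any extra variant in a truth
  gene would create sibling combinations exactly tied with the truth, and
  the worst-case tie rule would then never report rank 1;
* panel seed genes sit outside the exome's gene set — a seed node is by
  construction the most walk-proximal node, so a panel gene inside the
  candidate pool would trivially dominate DS and mask the planted signal.

Passing the planted-recovery and degradation tests shows the pipeline fuses
and ranks the two signals correctly under controlled conditions; it says
nothing about recovery rates on real patients, which depend on real
annotation quality, a trained combination classifier and a curated knowledge
graph.

## Verification

The iterative walk is checked against an independent dense linear solve
p = r(I − (1−r)W)⁻¹p⁰ on random mixed-type graphs (L∞ < 1e-6), plus the
hand-derivable two-node case (seed {A}, r = 0.3 → scores 0.3/0.51 and
0.21/0.51). Combination enumeration is checked against both the closed form
and brute-force subset enumeration. `scripts/acceptance.py` recomputes the
100-exome planted benchmark (with and without planted edges), the oracle
gap and the two-node score for any seed; problem sizes are as listed above.

## Known limitations

* No semantic similarity over the phenotype ontology and no seed expansion
  to ancestor terms; seeds are matched literally.
* The walk is blind to edge weights, directions and layer identity.
* No calibrated probabilities: ranks and scores are comparable within one
  exome only (scaling is strictly per exome).
* X-linked genotypes receive no special handling beyond the hemizygous→hom
  rule.
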