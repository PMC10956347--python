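# Methods

## Model overview

`netprio` treats drug prioritisation as a network problem on three
graphs: an undirected protein–protein interaction network (PPIN) over
integer gene IDs, per-cell-type disease modules (subgraphs induced by
differentially expressed genes, DEGs), and a directed, weighted
cell-type crosstalk graph (the multicellular disease model, MCDM).
Selection happens per cell type (proximity + counteraction), ranking
happens across cell types (two eigenvector centralities combined into
one compound score).

Only the largest connected component of the input PPIN is used;
self-loops and duplicate edges are dropped at load. Closest-distance and
centrality semantics are cleaner without self-loops, and distances are
always defined inside one component. All inputs must already share one
gene-ID space; ortholog mapping and DEG calling are upstream of this
package.

## Proximity screen

For targets *T* and in-network DEGs *S*, d_c = mean over *T* of the
BFS distance to the nearest member of *S* (DEGs outside the network are
silently excluded). Distances come from an all-pairs unweighted
shortest-path matrix cached on the interactome object; at screening
scale this makes each permutation a pure indexing operation.

The null randomises **both** sets per iteration, degree-matched: nodes
are sorted by degree, consecutive degree values are pooled until a bin
holds ≥ `min_bin` genes (default 100), and a trailing undersized bin is
merged into its predecessor. Each input gene is replaced by a draw from
its bin, without replacement within the sampled set. Sampling k distinct
members of a bin with `Generator.choice(replace=False)` is
distributionally identical to per-gene rejection sampling and is
deterministic under a fixed seed; requesting more draws than a bin holds
is an error rather than a silent fallback.

z_c uses the population standard deviation (ddof = 0) over `n_iter`
iterations (default 1000), so frozen golden values are stable. When the
null is degenerate (σ = 0, e.g. on a complete graph) z_c is NaN and the
drug cannot pass selection — fabricating ±∞ significance on degenerate
graphs would be worse than abstaining. Both cut-offs are strict
inequalities: z_c < −1.64, d_c < 1.

Reproducibility: each (cell type, drug) pair owns an RNG substream
derived from the global seed and a SHA-256 hash of the pair's labels, so
serial and `joblib`-parallel execution produce byte-identical tables.

## Counteraction filter

`counteracts(action, logfc)` is true iff (inhibit ∧ logfc > 0) ∨
(activate ∧ logfc < 0); unknown actions are conservatively false. The
filter keeps a candidate when at least one of its targets that is a DEG
of that cell type is counteracted; non-DEG targets are ignored, and a
drug with one counteracting and one aggravating target survives. Zero
fold changes are rejected at load, so the predicate never sees them.

## Intracellular centrality

The disease module is the largest connected component the cell type's
in-network DEGs induce in the PPIN; ties between equal-sized components
break to the component containing the smallest gene ID (an explicit
convention, chosen for determinism). A single-gene "component" counts as
isolated, i.e. the module is empty and all drugs score zero there.
Eigenvector centrality is computed by dense symmetric
eigendecomposition of the module adjacency and max-normalised to 1;
strict positivity (Perron–Frobenius on a connected graph) is asserted to
catch sign-flipped eigenvectors. A drug's score is the geometric mean of
its in-module target centralities — in-module membership, not mere DEG
status, is required — and the combined intracellular centrality is the
sum over cell types.

## MCDM construction

Background genes of a cell type are those with
Ea(i) = log₂(Σ_j 10^{D_ij}/k) ≥ 0.2 (inclusive) over its k cells, D
being the denoised log10-scale expression matrix. Negative expression
entries are clipped to 0 with a warning, as the Ea formula assumes
non-negative log10 values; an empty background is a fatal error for that
cell type.

For every ordered pair of DEG-bearing cell types (self-pairs included),
candidate ligands are the sender DEGs covered by the ligand–target
prior. Ligand activity is the Pearson correlation between the ligand's
regulatory-potential scores and the binary receiver-DEG indicator,
evaluated over (background ∪ gene set) ∩ prior genes — the gene set is
unioned in rather than required to pass the background cut-off, so the
indicator always has support. A universe of fewer than 3 genes is an
error; zero variance in either vector yields activity 0 with a warning.
Only positive activities enter the model; an edge's weight is their sum,
so removing one ligand interaction decreases exactly one edge weight by
exactly its correlation.

Cell-type centrality uses the receiver-importance convention: a node's
score is the weighted sum of the scores of nodes pointing to it
(principal eigenvector of the transposed adjacency), max-normalised.
When the directed spectrum is degenerate — a nilpotent or reducible
graph whose dominant eigenvector vanishes on nodes that do have edges —
the computation falls back to the symmetrised adjacency and logs the
fallback. Cell types touching no edge score 0. Self-interactions are
retained throughout.

Full ligand–receptor network filtering and target-gene prediction are
out of scope; the activity definition above is the part of the crosstalk
machinery the ranking consumes.

## Ranking and evaluation

Compound score = intercellular + 0.1 × combined intracellular; the
weight makes crosstalk importance dominant and intracellular centrality
an effective tiebreaker. Before ranking, drugs with an identical target
set and identical per-target action map are forced into one tie group
carrying the group's **maximum** compound score (the propagated score is
a convention; the maximum was chosen so grouping never penalises a
drug). Ranks are average positions over the full screened library, so
drugs selected by no cell type are still ranked — ordered by their
intracellular tiebreak, then lexicographically for display. Precision
and recall follow the standard set definitions; "top-k" means all drugs
with rank ≤ k, which with average ties can be larger or smaller than k.

## Synthetic benchmark

The generator emulates the post-processing interface the pipeline
consumes, not raw sequencing data: no counts, dropout or library-size
effects, so passing tests demonstrate correctness of the screening and
ranking machinery, not robustness to upstream noise.

Defaults: 400-gene preferential-attachment interactome (m = 2, hence
connected and degree-heterogeneous), 5 cell types × 60 cells, planted
connected 25-gene DEG modules grown by BFS from a random seed node,
|logFC| uniform on [1.5, 4] (matching the conventional DEG cut-off of
|logFC| ≥ 1.5) with a dysregulation direction drawn once per gene so
counteraction is unambiguous across cell types, adjusted p-values well
below a Bonferroni 0.05. Of 80 drugs, 20 are "good" (1–3 in-module
targets, counteracting with probability `frac_counteracting`, default 1)
and 60 are decoys — alternately degree-matched random-target controls
(unknown action on any DEG target) and in-module aggravators that mimic
an agonist of an upregulated disease gene. Module genes are expressed at
D ≈ 0.6 and a housekeeping stratum at D ≈ 0.4 (noise SD 0.1), so module
genes clear the Ea ≥ 0.2 background cut-off. The ligand prior plants one
ligand per sender→receiver pair around a cycle plus extra edges into the
first cell type (making it the crosstalk hub); planted rows mirror the
receiver module at high potential over low background noise. The
relevant-drug list is exactly the good drugs.

At this scale the permutation bin size defaults to 20 (the screening
default of 100 presumes a ~17,000-gene interactome) and benchmark runs
use 200 permutation iterations; both remain configurable everywhere.

## Numerical and degenerate-input conventions

- Permutation SD: population (ddof 0); σ = 0 ⇒ z undefined ⇒ not
  selected.
- Eigenvectors: dense (sym)eigendecomposition; |·| then max-normalise;
  positivity asserted on connected modules.
- DEG cap (`max_degs`): keep smallest adjusted p, ties by larger |logFC|,
  then smaller gene ID — an explicit convention where only "top
  significant" is specified.
- Duplicate (drug, target) rows: last action wins, with a warning.
- Equal-sized LCCs: smallest-gene-ID component wins.
- All thresholds (−1.64, 1.0, 0.2, 0.1, bin 100, 1000 iterations, top
  100) are exposed as parameters with these defaults.

## Known limitations

- The benchmark's planted signal is strong by construction; it validates
  mechanics and determinism, not statistical power at realistic effect
  sizes.
- The binary activate/inhibit action model cannot express dose-dependent
  or biphasic pharmacology.
- Ligand activity reduces crosstalk inference to its correlation core;
  receptor-expression filtering in the receiver is not modelled.
- The directed-centrality fallback (symmetrisation) discards edge
  direction on reducible graphs; such graphs are logged so users can
  inspect them.
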