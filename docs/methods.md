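# Methods

This note documents the models and procedures implemented in `ovatlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## The problem

Building a cell atlas from droplet scRNA-seq of a structured tissue —
here the adult *Drosophila* ovary serves as the motivating system —
requires (i) removing low-quality droplets and doublets, (ii) merging
replicate batches, (iii) partitioning cells into a *hierarchy* of types
whose top levels separate distantly related lineages (germline vs soma)
and whose lower levels separate close subtypes (escort-cell
subpopulations, follicle-cell stages), (iv) naming clusters from marker
genes, (v) ordering cells of a differentiating lineage in pseudotime,
and (vi) relating the transcriptomic populations to lineage-tracing
measurements made per ovariole and per fly. `ovatlas` implements each
stage as a library function with a thin CLI, and ships a generative
simulator so that every stage is testable against ground truth without
any external download.

## Synthetic data

`simulate.HierarchySpec` draws a scene from an explicit generative
model:

- **Baseline expression.** Per-gene baseline means are log-normal
  (`baseline_mean_log_mu = 0`, `log_sigma = 1`), spanning roughly two
  orders of magnitude, as in real UMI data.
- **Markers.** Every non-root node of the cell-type tree owns a disjoint
  set of `markers_per_node = 50` genes multiplied by
  `marker_fold_change = 8` in the node's cells *and all descendants* —
  marker planting is hierarchical, which is what makes coarse splits
  separate lineages and fine splits separate subtypes.
- **Exclusive lineage genes.** Graded 8-fold markers are not
  "mutually exclusive" genes: with realistic library-size spread their
  off-lineage tails overlap their in-lineage bulk, and no raw-count
  threshold separates them. Lineage-defining genes in real tissues
  (germline *vas*, somatic *tj*) are effectively on/off. The generator
  therefore suppresses the top `exclusive_genes_per_branch = 3` markers
  (by baseline) of each tier-1 branch to `exclusive_off_scale = 2%` of
  baseline outside their branch. The doublet rule is built on these
  genes, exactly as the vas/tj rule is in practice.
- **Counts.** Negative binomial with dispersion 0.25 (size 4; variance =
  m + 0.25 m²), a mid-range value for moderately expressed genes in
  droplet UMI data. Per-cell library sizes are log-normal with median
  2,500 UMI and log-sd 0.35; per-gene relative expression is scaled so a
  cell's expected total approximates its drawn library size.
- **Batches.** Each of `n_batches = 3` replicates multiplies every
  gene's mean by an independent log-normal factor
  (`batch_sigma = 0.1`), a deliberately simple multiplicative batch
  model: strong enough that correction is measurable, weak enough that
  replicate pseudobulk profiles still correlate (r² ≥ 0.96 in the
  standard scene).
- **Doublets.** `inject_doublets` appends `round(rate · n)` cells, each
  the gene-wise sum of two uniformly sampled parents from *distinct*
  tier-1 branches, binomially thinned to a library size resampled from
  the realized singlet totals. Same-branch doublets are out of scope:
  the implemented removal rule can only see cross-lineage co-expression.
- **Gradients.** `GradientSpec` draws per-cell positions t ~ U(0, 1);
  each monotone gene's mean is baseline · (1 + amplitude · g(t)) with
  g linear or sigmoid, reflected for "down" genes. The standard
  benchmark (`default_gradient_spec`) uses 300 of 2,000 genes at
  amplitude 10 — a strong differentiation continuum in which a large
  fraction of the transcriptome turns over, as in germline
  differentiation. Weaker gradients (e.g. 100 genes at amplitude 6)
  leave the embedding itself carrying only ρ ≈ 0.97 with truth, which
  caps any pseudotime method near 0.9.

What the simulator does **not** model: ambient RNA, cell-cycle
structure, sequencing errors, gene–gene correlation beyond the planted
types, zero inflation beyond NB sampling, or realistic gene counts.
Passing benchmarks on these scenes demonstrates that the algorithms
recover planted structure under calibrated noise; they do not guarantee
performance on any particular real dataset.

## QC

Cells are filtered on total UMI and detected genes
(`QcThresholds`, defaults min_umi = 500, min_genes = 200, no upper
bounds). These defaults separate a debris mode at ~10% of a normal
library from intact cells; they are configuration, not constants, and
real datasets should set them from their own QC distributions.
Doublets are flagged when a cell's raw counts reach per-gene thresholds
for *both* genes of any declared `ExclusivePair`. Thresholds operate on
raw UMI counts — the co-expression rule is binary and needs no depth
normalization. For simulated scenes, `pairs_from_branch_markers` plays
the role of biological knowledge: it reads the generative record and
sets each gene's threshold at the 0.999 quantile of its off-lineage
negative-binomial distribution (evaluated at the median library size).

## Normalization, embedding, integration

Expression is normalized to ln(1 + UMI/total × 10⁴) (log1p of
counts-per-10k). Variable genes are ranked by dispersion
(variance/mean of normalized values) z-scored within 20 equal-frequency
mean bins; ties break lexicographically so selection is deterministic.
PCA standardizes genes (clip at ±10) and fixes each component's sign by
making its largest-magnitude loading positive. Batch integration is
per-batch centroid alignment in PC space: every batch is translated so
its mean coincides with the global mean. This is transparent, exactly
preserves within-batch geometry, and suffices for multiplicative batch
noise; it is *not* an anchor-based method and will not correct
batch effects that differ per cell type. Replicate agreement is
quantified as squared Pearson correlation of per-batch pseudobulk
(mean normalized expression per gene).

## Tiered clustering and the quality gate

The core procedure clusters the whole dataset, checks the split with a
differential-gene gate, and recurses into every accepted subcluster,
producing dotted tier labels ("1.0.2") whose k-th prefix is the tier-k
cluster.

**Node clustering.** Each node is re-embedded locally (variable genes
and PCs recomputed within the node — global components wash out fine
subtypes), a shared-nearest-neighbor graph is built (k = 20, Jaccard
weights over kNN sets, pruned below 1/15), and Leiden modularity
optimization is run over a resolution grid (0.1 … 1.2), taking the
*lowest* resolution that yields ≥ 2 communities — the coarsest split
first.

**Binary tier coarsening.** When the types under a node are strongly
separated, the SNN graph decomposes into disconnected components and
Leiden returns all of them at *every* resolution — modularity-type
objectives never merge disconnected communities, so the resolution
parameter cannot produce coarse tiers on well-separated data. To keep
tiers genuinely coarse-to-fine, `run_tiered_clustering` (flag
`binary_tiers`, default on) coarsens a >2-community partition to the
top bifurcation of an average-linkage dendrogram over community
centroids: each tier separates the two most distantly related groups,
and recursion recovers the finer structure. With hierarchically planted
markers the centroid geometry orders merges correctly (sibling leaves
share their parent's markers and are closer to each other than to any
outgroup, distance ratio √(150/100) in the standard scene).

**Quality gate.** A candidate split is ratified only if *every*
subcluster shows at least Q = 5 genes that are (i) significant by
two-sided Wilcoxon rank-sum against the union of its siblings at
BH-adjusted p < 0.05, (ii) up-regulated with log2 fold-change ≥ 1 on
the expm1 scale (a `gate_two_sided` flag counts either direction), and
(iii) expressed in ≥ 25% of the subcluster's cells. Subclusters with
fewer than 3 cells fail automatically. Only the ≥ 5-gene contract is
fixed; the test, thresholds, and sibling-vs-rest comparison are
configuration. Nodes smaller than `min_cells_to_split = 50` cells, or
deeper than `max_depth = 5`, are terminal.

**Supervised splits.** Rare populations below the gate's reach are
split off explicitly: `split_cluster_by_marker` divides a terminal node
at a normalized-expression threshold on one gene and flags both
children "supervised".

Sibling order is by decreasing size with ties broken by the smallest
member cell id, and Leiden is seeded, so the whole tree is
deterministic for a fixed config.

## Markers

`rank_markers` tests one cluster against all other cells (Wilcoxon
rank-sum, BH across genes, fold-changes on expm1-scale means with a
10⁻⁹ pseudocount; all-zero genes get p = 1, lfc = 0 by convention).
"Most unique" genes are defined by a margin: a gene belongs to the
cluster where its mean normalized expression is highest, and its
uniqueness there is the margin over the runner-up cluster's mean. This
is a deliberate, documented stand-in for a visual "cluster-exclusive"
ranking; it is a function of per-cluster mean profiles only, hence
invariant to cell order. Cluster annotation scores each cluster against
a signed reference (mean z-scored expression of "+" genes minus "−"
genes) and assigns the argmax type when its margin over the runner-up
reaches `min_margin` (a single-type reference is compared against a
zero baseline). Gene-set scores subtract expression-matched controls
drawn per bin of average expression (25 bins, 50 controls per bin,
seeded), so a whole-genome set scores exactly zero.

## Pseudotime

The trajectory backbone is a minimum spanning tree over cluster
centroids (seeded k-means groups when no clustering is supplied) in a
deliberately low-dimensional embedding — top 3 PCs of 500 variable
genes by default; extra noise dimensions make the centroid MST snake
and degrade the ordering. Cells project onto the nearest backbone
segment; pseudotime is geodesic distance from the root endpoint,
min-max scaled to [0, 1]. The root is chosen either as an explicit cell
or as the degree-1 backbone endpoint whose projected cells show the
extremal mean expression of a marker (e.g. the low end of a
differentiation gene marks the stem end). This centroid-MST
construction replaces principal-graph learning: simpler, deterministic,
adequate for linear or mildly branched trajectories, and documented as
a stand-in.

Cells are then sorted by pseudotime (stable ties by cell id) and
chunked into fixed bins of 10 cells; the trailing partial bin is kept.
Expression profiles are per-bin means, optionally smoothed by a
centered moving average, then min-max scaled per gene for heatmap
export (constant genes map to zero). Pseudotime-dependent genes are
detected by Spearman correlation with BH adjustment — rank-based to
match monotone but nonlinear responses; under a simulated null its raw
p-values are calibrated at α = 0.05 within sampling error on 2,000
genes.

## Lineage statistics

Clone tables record one category per ovariole. Proportions are tallied
per condition; the S.E.M. is computed across flies (the biological
replicate), undefined for a single fly. Frequency comparisons use the
classical pooled-variance two-sample Student's t (df = n₁ + n₂ − 2) on
per-fly frequencies — Welch's correction is intentionally not the
default because the equal-variance form is the field convention for
these comparisons; degenerate zero-variance input follows explicit
conventions (equal means → t = 0, p = 1; unequal → p = 0 with a
warning). Census tables summarize per-germarium counts as mean ± SD
(n − 1), with between-marker differences optionally rounded to whole
cells. The coverage ratio is total profiled cells divided by cells per
anatomical unit.

## Numerical conventions

- Wilcoxon rank-sum p-values use the tie-corrected normal
  approximation; constant genes get p = 1.
- BH adjustment is applied within each comparison, across genes.
- Spearman p-values use the t approximation with n − 2 df.
- MST edge lengths are floored at 10⁻¹² so duplicate centroids remain
  representable; ties resolve by label order.
- All stochastic steps (simulation, Leiden, k-means, control-gene
  draws) take explicit seeds; identical spec + seed is bit-identical.

## Benchmark problem sizes

The standard benchmark scenes are sized for a laptop-class run: the
nested hierarchy is 900 cells × 2,000 genes × 3 batches (300 cells per
leaf), gate-specificity trials use 1,000 × 2,000 homogeneous matrices,
gradient scenes 500 cells × 2,000 genes. The acceptance script runs 20
tier-recovery seeds, 100 gate trials, 20 gradient seeds, and 1,000
t-test oracle cases in a few minutes.

## Known limitations

- Centroid-mean batch alignment cannot fix type-specific batch effects.
- Binary tier coarsening imposes two children per tier; a genuinely
  k-way equidistant split appears as a cascade of binary tiers (the
  terminal partition is unaffected).
- The centroid MST cannot represent cyclic or densely branched
  trajectories.
- The uniqueness margin depends on the cluster granularity supplied to
  it; over-merged clusters dilute their markers' margins.
- The exclusive-pair doublet rule only sees cross-lineage doublets;
  within-lineage doublets need a density- or simulation-based score,
  which is out of scope.
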