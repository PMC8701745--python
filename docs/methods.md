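# Methods

This note documents the models, defaults and design choices behind
`dcmpanel`, and what the synthetic benchmarks do and do not establish.

## Synthetic cohort model

Counts are negative binomial with mean μ and dispersion φ
(variance μ + φμ²; φ = 0 degenerates to Poisson).  The generator is
compositional, as sequencing is: each gene carries a relative abundance
weight 2^b (b = "baseline log2 mean"), a sample's expected count is its
library depth times the gene's share of the summed weights, and library
depths are log-normal (sd 0.2 on the natural-log scale) around 10⁷.
The normalizing constant is computed once from the baseline weights, so
a planted log2 fold change Δ on a gene makes the DCM/HS ratio of
generating means exactly 2^Δ (`expected_means` exposes the pre-noise μ
matrix for oracle checks).

Defaults mirror the target cohort: 11 samples per group, two source
batches (the tail of each group, 2/11 disease and 4/11 control samples,
comes from batch "B" with an additive +0.5 log2 shift applied to all
genes), dispersion φ = 0.1 — at the low end of what is reported for
human inter-individual bulk RNA-seq, chosen so that planted effects of
|Δ| ≥ 1.5 are strong but not trivial at n = 11.  Clinical covariates
are linear in a designated gene's log2 expression plus Gaussian noise;
monotonicity (all Spearman can detect) is therefore exactly controlled.

Because a batch shift applied uniformly to *all* genes multiplies every
count in the sample and cancels in CPM, the residual post-CPM batch
signal is small; the location correction removes what remains without
using group labels.

### Named benchmarks (study conditions, fixed)

* **strong-signal** (`strong_signal_spec`): 2,000 genes, 5 planted
  effects at log2FC {+2.5, −2.4, +2.1, −1.8, +1.5} on well-expressed
  genes.  Abundance is bimodal, as in striated muscle where a small set
  of sarcomeric/mitochondrial transcripts dominates the library: ~92.5%
  of genes at log2 weight 0.5–2.5 (below ~1 CPM, where whole k-means
  clusters fall under the detectability threshold) and a 7.5% expressed
  minority at 11–18.  Two covariates (LVEDD, LVESD) are linked to the
  two strongest planted genes with noise 0.25× the expression sd.  The
  benchmark is single-batch: it isolates selection-cascade and
  splitting-criterion behavior, while batch handling is exercised by
  the generator default and the preprocessing/leakage tests.  With a
  two-batch design the per-fold re-estimated batch offsets move every
  batch-B value by ~0.3 log2 whenever a batch-B sample is held out,
  and the tree census then measures offset jitter rather than criterion
  stability.
* **null** (`null_spec`): identical groups, no effects, single batch;
  used for type-I calibration.
* **planted-FDR** (`planted_fdr_spec`): 10% of genes at |log2FC| = 2 on
  moderately expressed genes (log2 weight 2.5–5).  Planting strong,
  unbalanced effects on the *most abundant* genes instead shifts
  library composition and biases every null gene's CPM fold change —
  a known failure mode of total-count normalization (the reason TMM /
  median-of-ratios exist, both out of scope here), not of the test.

## Preprocessing

Expression is log2(CPM + 1); the pseudocount keeps zeros at 0 and all
values non-negative.  Library sizes are total reads per sample computed
*before* gene filtering, so a sample's normalized values are identical
in every cross-validation fold that contains it.  The candidate-gene
filter keeps genes with count ≥ 10 in ≥ 25% of samples (both
configurable; the rule is a standard detectability heuristic).  Batch
correction is gene-wise location adjustment — every batch mean is
shifted to the gene's global mean.  Group labels are deliberately not
used: in the motivating design, batch is partially confounded with
group, and a group-aware adjustment would leak labels into every
downstream stage.

## Differential expression

Welch's *t* on log2(CPM+1) per gene; log2FC is the difference of group
means (DCM − HS).  At equal group sizes the statistic is robust to the
skewness that survives the log transform, and on the null benchmark the
observed fraction of p < 0.01 is statistically indistinguishable from
0.01 (pooled over 40,000 gene tests).  Zero-variance genes follow a
deterministic convention: equal means → p = 1; unequal means → p = 0
with a warning.  Multiple testing is Benjamini–Hochberg step-up,
implemented directly and tested against an independent oracle.  DEG
tiers use strict inequalities: p < 0.01, and FDR < 0.05 with
|log2FC| > 1.

## Selection cascade

* *k-means* (k = 100 by default): genes are points, samples are
  dimensions.  Deterministic: k-means++ seeding from the fold's
  sub-seed, lowest-index tie-breaks, empty clusters reseeded with the
  farthest point, assignment-fixed-point convergence, exact member-mean
  centroids on exit.
* *Detectability* (τ = 1.0 on log2(CPM+1), i.e. ~1 CPM): drop every
  cluster whose centroid never reaches τ in any sample; genes are
  removed cluster-wise, not individually.
* *Fold change* (δ = 0.5): keep genes with |Δ mean log2| ≥ 0.5.  The
  threshold is on the log2 scale; a raw-ratio reading of 0.5 would be a
  2-fold change and anything but permissive.
* *Frequency* (f_min = 0.75): after all folds complete, a gene's
  frequency is the fraction of folds whose post-fold-change set
  contains it; the aggregate panel keeps genes at frequency ≥ 0.75,
  sorted by frequency then id.

The cascade contracts monotonically per fold (cluster ⊇ FC ⊇ final).
On the strong-signal benchmark the per-fold stages retain on average
~250 genes after the cluster filter and ~6 after the fold-change
filter, and the final panel (5 planted genes plus occasional
passengers) has every planted gene at frequency 1.0.

## Decision trees and the census

Trees are binary and axis-aligned; leaves carry majority labels with
training support counts (label ties go to DCM and are logged).  A node
becomes a leaf when pure, at max_depth (default 3), below min_leaf
(default 2) or when no split improves Gini impurity.

**Standard criterion** — best Gini gain over thresholds at midpoints of
adjacent distinct values; ties resolved by data order.  This is
deliberately order- and sample-sensitive: it reproduces the fragility
of off-the-shelf tree induction under leave-one-out retraining.

**Stable criterion** — the split partition is still chosen by maximal
Gini gain, but thresholds and tie-breaks are chosen to be invariant
under single-sample deletion wherever possible:

1. the threshold is placed inside the widest value gap consistent with
   the optimal partition, at the *simplest dyadic value* — the m·2^j
   with the largest 2^j strictly inside the gap, nearest the midpoint.
   Deleting a non-boundary sample leaves the gap unchanged; deleting a
   boundary sample only enlarges it, and the snapped value survives
   unless a strictly coarser dyadic enters the enlarged gap.  A raw
   midpoint, by contrast, moves every time a boundary sample is
   dropped.
2. gain ties break by higher cross-fold frequency prior, then
   lexicographic gene id, then wider margin.  Sample-invariant keys
   outrank the noise-sensitive margin, so near-identical training sets
   agree on the split gene.
3. candidate genes are the fold's slice of the aggregate panel, with
   the aggregate frequency table as the prior (second training pass).

The census partitions the per-fold trees into node-for-node equality
classes (threshold tolerance 10⁻⁹) and draws a specialization edge
between classes when one representative collapses onto the other
(subtrees replaced by strict support-weighted majority leaves).  On the
strong-signal benchmark the standard criterion typically yields 3+
distinct types while the stable criterion yields 1 (occasionally 2);
across 20 benchmark cohorts the stable census is never larger than the
standard one.

The true splitting-criterion modification this reconstruction stands in
for is not published in detail; the criterion is isolated behind the
``criterion=`` interface so an alternative definition can be swapped in
without touching the census or the orchestration.

## Leave-one-out orchestration

Two passes.  Pass 1 re-runs candidate filtering, normalization,
batch-offset estimation and the cluster/FC stages on each fold's
training samples only; the held-out sample's values cannot influence
its own fold's selection (audited by perturbation tests).  Pass 2
aggregates frequencies, fixes the panel, and trains both trees per fold;
the held-out sample is classified by the stable tree.  Per-fold seeds
derive from the master seed via `SeedSequence`, and identical inputs +
seed give byte-identical serialized results.

Known limitation: the aggregate panel pools all folds, so each sample
influences the panel through the other n−1 folds (its own fold's
cluster/FC stages remain untouched).  This mirrors the single
cross-fold panel the two-pass design is specified to produce; a fully
nested variant would re-aggregate within every fold at n× the cost, and
LOO accuracy under label permutation is nevertheless consistent with
chance (mean over 20 permutations within 3 SEs of 0.5).

## Clinical association

Spearman ρ uses midranks.  Two-sided p-values are exact for n ≤ 8 —
full enumeration of all n! permutations of the observed midrank vector
— and use the t approximation t = ρ√((n−2)/(1−ρ²)), df = n−2 above.
Screening keeps |ρ| > 0.5 (strict) with p ≤ 0.05 (inclusive: a pair at
exactly p = 0.05, which the exact null distribution can produce at
small n, counts).  No multiple-testing correction is applied to the
pass flag — the grid is a screen, not a confirmatory analysis — but a
BH column is emitted alongside.  An optional stratum filter
(`"NYHA=3"`) restricts samples before correlating, with n ≥ 3 enforced.

## Enrichment and subnetwork

Over-representation is the hypergeometric upper tail P(X ≥ k) by direct
pmf summation, sets intersected with the universe first, BH across
sets; gene sets are flat GMT (no ontology DAG propagation).  Subnetwork
extraction keeps edges with score strictly above the floor (default
0.7), channel in the requested subset, and at least one endpoint among
the seeds.

## Numerical conventions

Gini gains compare with tolerance 10⁻¹²; census thresholds with 10⁻⁹.
Exact permutation counts use a 10⁻¹² slack when comparing |ρ| values.
k-means inertia is recomputed from exact centroids at exit.  All
randomness flows through `numpy.random.Generator` seeded from explicit
integers; no global RNG state is touched.

## What the benchmarks do and do not show

The synthetic cohorts have independent genes (beyond compositional
coupling), log-uniform abundance tiers, and purely additive batch and
covariate structure.  Passing tests demonstrate correctness of the
implemented procedures and their claimed stability/calibration
properties under these controlled conditions — not that the selected
panels or the qualitative census behavior transfer to any real cohort,
where gene–gene correlation, batch–group confounding and heavy-tailed
dispersion are all stronger.
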