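# Methods

## Design overview

`telosig` asks whether a focal cell type, observed at two timepoints, has a
gene-expression signature on one chromosome that separates it from a panel of
other cell types, when the underlying measurements come from several
microarray datasets with different overall scales. The method is deliberately
simple — group means, a fold statistic, multi-threshold counting, and
all-comparisons intersection — because the questions it answers are set
membership questions ("which genes are up in the focal type against *every*
other type?"), not significance questions. No variance-based test statistic is
used anywhere; replication enters only through the per-group mean.

## Harmonization model

Each sample j is modelled as

    B_ij = μ_i(g(j)) · s_d(j) · 2^ε_ij,   ε_ij ~ N(0, σ²)

where μ_i(g) is the true linear mean of gene i in sample group g, s_d is a
single multiplicative scale per source dataset d, and ε is log-normal
measurement noise. Two steps target the two nuisance terms:

* **Quantile normalization** (within each source dataset) forces all columns
  of a dataset to the row-wise mean of their sorted values. Ties within a
  column receive the mean of the target values their ranks span; this makes
  the operation deterministic, column-sum preserving, and idempotent.
  Normalizing within rather than across datasets keeps the cross-dataset scale
  factor intact for the next step to estimate, and is recorded as the default
  stage order in the run manifest.
* **Housekeeping scaling** estimates s_d from genes assumed equally expressed
  in every cell type. Y_j is the housekeeping mean of column j, C the grand
  mean of Y over the *reference* samples (the samples of the designated
  reference dataset, whose scale defines the common unit), Z_j = 1 for
  reference samples and Y_j / C otherwise, and E = B / Z. Z is a ratio of
  means, so when noise is zero the batch factor is removed exactly — a
  property the tests assert to 1e-10 relative error. Within-column gene ratios
  are untouched by construction. The housekeeping set and reference samples
  are user-supplied (the synthetic generator supplies its own); no default
  housekeeping list ships with the package.

**Median polish** (probe summarization) fits value ≈ overall + probe + sample
by alternating row/column median sweeps (row sweep first, effects re-centred
by their median into the overall term), stopping when the largest median
removed in a sweep is below 1e-8 or after 100 sweeps. The sweep order is part
of the contract: median polish fixed points are not unique, so the tests'
independent oracle codes the same convention with different machinery.

## Fold statistic

With pseudocounted group means a′ = a + ε and b′ = b + ε (ε = 1 intensity
unit by default, guarding near-zero means on microarray scale):

    f = +(a′ − b′)/b′  if a′ ≥ b′,   else  −(b′ − a′)/a′.

This symmetric relative difference is antisymmetric (f(a,b) = −f(b,a)), zero
iff a = b, and satisfies f > t ⇔ a′ > (1+t)·b′, so the "more than onefold"
threshold equals the conventional two-fold-ratio cut. A literal one-sided
variant that always divides by the focal mean is available
(`formula="literal"`) but cannot exceed 1 in the up direction whenever the
other mean is positive — which is why it is not the default. Thresholds use
strict inequality. Folds are always computed on the linear scale after all
normalization; log2 matrices are exponentiated first.

## Signature and counts

The per-comparison count grid counts genes with f > t (up) or −f > t (down)
for t ∈ {1, 2, 5, 10}; counts are necessarily non-increasing in t, a
structural invariant the tests check on every generated dataset. Combined
rows ("TCs versus X") count genes passing in **both** focal timepoints.

The specific signature keeps genes passing the threshold against *every*
other group, combined across timepoints with rule `both` (default) or
`either`. The default is `both` because the combined count rows imply an
intersection; `either` is exposed since a gene present at day 5 *or* day 10
is also a defensible reading of "specific". A gene qualifying up under one
timepoint and down under the other (possible only under `either`) is
contradictory and dropped from both sets. Top-k ranking orders by |f|
descending with lexicographic symbol tie-break, so results are reproducible
across runs and platforms.

## Clustering

Samples are clustered on d = 1 − Pearson r computed across the union of
differential genes (all genes passing the lowest threshold in any
comparison), on log2 values: the log transform keeps the correlation from
being dominated by a handful of bright genes. Agglomeration is a plain O(n³)
loop (n = number of samples, tens at most) with average linkage by default
and a deterministic tie-break — among minimum-distance cluster pairs, the one
whose sorted leaf labels compare lexicographically smallest merges first.
Dendrograms serialize to Newick with ultrametric branch lengths (leaf depth =
half the root merge height). scipy's agglomerator is used as an independent
oracle in the tests, never as the implementation, because scipy does not
guarantee this tie-break.

## Enrichment and network

Over-representation of a signature in a user-supplied gene-set collection
(GMT format) uses the upper-tail hypergeometric probability P(X ≥ k) for
X ~ Hypergeom(N, K, n) via `scipy.stats.hypergeom.sf`, with
Benjamini–Hochberg adjustment across the collection
(`statsmodels.stats.multitest`). The test is one-sided by design: enrichment
here means over-representation. The co-expression network is a local,
data-driven companion to external protein-association queries: an edge joins
two genes with |Pearson r| ≥ 0.8 (default) across samples; zero-variance
genes are excluded with a warning. Signatures also export as plain
newline-delimited symbol lists for pasting into external multi-protein query
forms — no web service is contacted.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* of the merged collection the pipeline
targets: 645 genes on a focal chromosome among 10,000 background genes spread
over chromosomes 2–19; eight cell types, the focal one contributing two
timepoint groups (nine groups, three replicates each by default — the source
series carried one to three replicates per group, so three is a realistic
upper choice); four source datasets (the focal platform carrying the focal
type plus the two stromal types, and three public series carrying the
epithelial and lymphocyte types), each with one multiplicative batch scale;
baseline expression log-normal with log2 mean 8 and SD 2 (typical microarray
intensity spread); log-normal noise with σ = 0.2 on log2 scale by default.
Planted effects: 14 up- and 39 down-regulated focal-type genes at linear
ratio 3 (the design the recovery experiments use), active in both timepoints
unless `planted_timepoints` restricts them to one; 20 housekeeping genes with
identical means in every group; and 30 marker genes per non-focal type on the
focal chromosome, without which the other cell types would be mutually
indistinguishable after the chromosome restriction and no per-type clade
structure could exist. A marker separates its own type from the focal type in
exactly one comparison, so markers never contaminate the all-comparisons
signature.

Deliberate simplifications: batch effects are a single scalar per dataset
(no gene-specific platform effects), noise is homoscedastic on log2 scale
(no intensity-dependent variance), probes map to genes without cross-
hybridization (the optional k-probes-per-gene expansion adds only a fixed
per-probe affinity), and the two focal timepoints share identical true means.
Passing recovery tests therefore shows the pipeline's logic is correct under
its own model assumptions — it does not show robustness to gene-specific
platform bias, which no housekeeping scalar can remove. Because the
timepoints are exchangeable by construction, the clustering tests assert
per-*cell-type* clades (all six focal samples together) rather than
per-timepoint clades, which are not statistically guaranteed.

## Numerical and degenerate-input choices

* Quantile normalization requires ≥ 2 columns; a single-sample dataset passes
  through unchanged with a warning at the pipeline level.
* Median polish: tol 1e-8, max 100 sweeps; single-probe blocks return
  unchanged.
* Housekeeping scaling refuses a zero housekeeping mean rather than guessing.
* Missing values are rejected at parse time; no imputation is performed.
* Probe collapse defaults to the arithmetic mean (scale-stable,
  order-independent); collapsed rows keep first-occurrence symbol order.
* Chromosome labels are opaque strings; no genomic coordinates are used.
* Pseudocount ε = 1.0 linear unit; fold thresholds {1, 2, 5, 10}, strict.
* All randomness flows from a single integer seed via
  `numpy.random.default_rng`; identical configuration and seed produce
  byte-identical pipeline outputs (the manifest contains no timestamps).

## Problem sizes

The test suite exercises unit behaviour on small matrices and the end-to-end
properties at the full design scale (10,645 genes × 27 samples); the noisy
recovery experiment uses 20 seeded replicates of that scale, and the
acceptance script repeats the same computations from scratch. These sizes are
the study design itself, not a reduction.

## Known limitations

* The housekeeping model removes only multiplicative per-sample scale;
  additive background or gene-specific platform effects pass through.
* Fold-based selection has no error control; the threshold grid is
  descriptive. The enrichment stage is the only inferential step.
* The GEO series-matrix reader handles the single-table text layout only; raw
  CEL/.pair files are out of scope.
* The co-expression network is correlational and undirected; it is not a
  protein–protein association network.
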