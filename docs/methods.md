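# Methods

This note documents the statistical models, the synthetic-data generators
that stand in for the study cohorts and slide scans, the numerical choices,
and the known limitations of `brainaging`.

## Study design being modeled

The pipeline targets a multi-region post-mortem brain cohort in which each
individual contributes log2-scale expression profiles from up to ten brain
regions (FCTX, TCTX, OCTX, WHMT, CRBL, SNIG, PUTM, THAL, HIPP, MEDU) and an
age between 16 and 106 years. Samples fall into three fixed age groups —
young 16–44, middle 45–74, old ≥ 75 years — which partition the adult range.
The companion imaging arm quantifies immunolabeled frontal-cortex sections
as RGB tiles in which the cells of interest carry a brown DAB chromogen
(OLIG2 or NeuN) and all other nuclei a blue hematoxylin counterstain.

## Differential expression and regional breadth

Within each region, every gene is tested by one-way fixed-effects ANOVA of
log2 signal on the three age groups. The F statistic is computed from
between/within sums of squares in closed form; groups with fewer than two
samples are dropped, and a region with fewer than two usable groups marks
all its genes untestable (NaN). Degenerate cases are handled explicitly:
zero within-group and zero between-group variance gives F = 0, p = 1;
perfect separation (zero within-group variance, unequal means) gives F = ∞
with p reported as 0.

P-values are adjusted per region across genes by Benjamini–Hochberg step-up
(the field default for expression arrays; the multiplicity family excludes
untestable genes). The significance threshold defaults to q < 1e−3 and is
configurable. Old-minus-young mean log2 difference supplies the effect
direction; an exact tie is reported as `none` and never counted as up or
down.

Genes are classified by the number of regions in which they are significant:
region-specific (1), region-selective (2–7), multi-regional (≥ 8),
cross-regional (all 10), with genes significant nowhere left unclassified.
The cut-points are defined for the ten-region design; any other region count
requires explicit thresholds rather than silent rescaling. The categories
partition the significant genes and are invariant to region ordering.

Gene-level summarization collapses probe sets to one row per transcript by
the per-sample median (the even-count convention is the mean of the middle
pair). Over-representation of a gene set within a breadth category uses the
one-sided hypergeometric tail; the reported odds ratio is the sample odds
ratio of the 2×2 membership table.

## Cell-type specificity

The reference panel is a gene × cell-type table of mean linear-scale
expression for seven CNS cell types (neurons, astrocytes, OPCs, newly
formed and myelinating oligodendrocytes, microglia, endothelial cells). The
specificity score of gene g for type t is

    score(g, t) = (mean_t + ε) / (max over other types + ε),

with pseudocount ε = 1 on the linear scale. This ratio-to-max definition is
the strictest common specificity measure: a flat gene scores 1 everywhere
and at most one type can exceed 1, so thresholding at any value > 1 yields
disjoint marker lists automatically. The default marker threshold is 5,
chosen so that markers at typical fold-enrichments (~20×) are recovered
while bounded cross-type jitter (< 2×) is excluded. The score is invariant
to global rescaling of the panel when ε is scaled proportionally. Consensus
lists are plain per-type intersections with a second, user-supplied list
collection. The reference and the study are assumed to share a gene
namespace; ortholog mapping between species is the caller's responsibility.

## Sample classification

Sample–sample similarity is Spearman rank correlation over a stated gene
subset (constant profiles give NaN off-diagonal). Clustering is
agglomerative on Euclidean distance with complete linkage by default
(stable for expression heatmaps; any scipy linkage is accepted), exported
to Newick when needed. Embedding is 2-D t-SNE (perplexity 30, 1,000
iterations, PCA initialization, fixed seed), requiring n > 3·perplexity.

"Successful discrimination" is operationalized as: cut the sample dendrogram
into three clusters, map clusters onto age groups by the assignment that
maximizes sample-level agreement (exhaustive over the 3! mappings, so the
score is invariant to cluster relabeling), and call an individual correct
when the modal mapped group of its samples equals its true group (ties
broken by sample count, then young < middle < old). Under random clustering
this best-of-six mapping inflates chance accuracy slightly above 1/3, which
the tests verify by simulation. Heatmap standardization is a per-gene
z-score using the population SD (zero-variance rows become zeros), clipped
to ±3 by default.

## Stepwise age model

Age in years is regressed on gene expression by forward–backward stepwise
OLS. Dummy-coded brain-bank and cause-of-death covariates are forced in and
never removable (redundant dummy columns are dropped with a warning).
Candidate terms are gene main effects plus, when enabled, pairwise products
of already-selected genes; restricting the interaction pool to selected
genes keeps the search desk-scale, with the consequence that an interaction
whose constituent genes have truly null main effects is unreachable — the
same hierarchy property as MATLAB-style stepwise regression. The entry
criterion is the partial-F p-value (add the best candidate when p <
entry_p, default 0.05); removal drops any term whose p exceeds removal_p
(default 0.10). Requiring entry_p < removal_p and forbidding immediate
re-entry of a just-removed term guarantees termination; `max_terms`
(default 20) bounds the model size. An AIC mode replaces both thresholds
with an information-criterion improvement rule. R² is non-decreasing
during a forward pass and the final R² is never below the covariate-only
R². The estimator follows the scikit-learn contract (`fit`/`predict`,
`get_params`, trailing-underscore attributes) and per-cell-type fits are
ranked by R² with ties broken by fewer gene terms.

## Tile quantification

QC entropy is the Shannon entropy (bits) of the 256-bin histogram of the
Rec. 601 luma grayscale; it spans [0, 8] for 8-bit images and tiles with
entropy ≤ 5 bits are excluded as uninformative. Segmentation proceeds as:
Otsu threshold on the grayscale to separate cells from the pale background;
per-pixel stain class (brown where R − B > δ, default δ = 20; blue
otherwise), with an alternative H-DAB color-deconvolution mode; binary
opening with a radius-2 disk; 8-connected components; discard of components
below 50 px; object class by majority pixel vote. Centroids are pixel
coordinates, origin top-left, x rightward, y downward. Per tile,
stained + other = total always holds.

Cell bodies are binned by area: small [500, 3,000), medium [3,000, 6,000),
large [6,000, 9,000] and very large > 9,000 pixels. Bounds are
lower-inclusive/upper-exclusive except that `large` includes exactly 9,000,
forced by the "> 9,000" definition of the top bin; objects under 500 px are
counted in totals but excluded from every bin, and the bins partition
[500, ∞). Density classes proxy white matter (few nuclei) versus gray
matter (many): tiles are ranked by total nucleus count (stable ties by tile
id) over the pooled distribution, the bottom third is `low` and the top
third `high`; within each class the k most extreme tiles per case (default
k = 50) are selected, and a shortfall selects all with a logged warning.

## Permutation statistics

Young-vs-old count differences use the pooled-variance two-sample t, signed
young − old so that positive t means higher counts in young samples. The
null is built by label shuffles; a scheme bundles the number of resampling
rounds, shuffles per round, the tail, an optional per-group tile subsample
drawn per round, and the seed — accommodating the workflow dialects of 100
rounds × 500 shuffles, 10,000 shuffles, or 100,000 shuffles. The reported
observed t is the mean true-label t across rounds, and the null pools
rounds × shuffles values. P-values use the add-one (Phipson–Smyth)
convention p = (1 + #{t_null ≥ t_obs})/(1 + N), so p is never 0 and its
minimum is 1/(N + 1); the two-tailed p is the doubled smaller tail, capped
at 1. Tiles, not cases, are the exchangeable units, mirroring per-slide
count statistics; case-level clustering is therefore not modeled, a caveat
for real designs with few cases. An exhaustive-enumeration oracle covers
small designs (≤ ~12 tiles) and the Monte-Carlo p converges to it within
binomial error, which the tests check.

## Synthetic-data generators

The generators define the conditions under which the pipeline is validated,
with ground truth carried alongside the data.

**Expression cohorts.** Each gene has a baseline drawn N(8, 1) log2 units.
Ages are drawn uniformly over 16–102 integer years, so group sizes are
unequal as in a real cohort. Each individual's sample for a region is
dropped completely at random at rate 0.08, reproducing the shape of a
cohort in which 134 individuals contribute 1,231 of a possible 1,340
region-samples; bank labels follow the 99:35 source split and sex and
cause-of-death are uniform. Regional identity enters as per-(region,
gene-block) log2 offsets (default SD 0.25 over 20 blocks). A planted aging
effect shifts the old-group mean by a chosen log2 amount in its affected
regions with the middle group at the midpoint — the simplest monotone trend
consistent with three ordered groups. Measurement noise is iid Gaussian,
default SD 0.5 log2 units. With no planted effects the per-gene ANOVA
p-values are uniform, which the tests verify by Kolmogorov–Smirnov at
5,000 genes.

**Reference panels.** Each gene gets a base level uniform on [20, 200] with
per-type jitter uniform on [0.7, 1.3], so non-marker ratio-to-max scores
stay below ~1.9 and never mimic markers. A planted marker's home-type mean
is exactly `marker_fold` (default 20) times its maximum over the other six
types before noise; multiplicative log-normal noise (σ = 0.05) follows.

**Tiles.** Stained and counterstained cells are flat-colored disks —
DAB-like brown (150, 100, 60) and hematoxylin-like blue (70, 85, 150) on a
pale background (235, 230, 225) — with radii uniform on 8–20 px, plus iid
Gaussian RGB noise (SD 3). Disjoint placement uses rejection sampling with
a bounded attempt budget (failure raises an error naming the achieved
count) and keeps a 2-px separation margin so that rasterized boundaries
never become 8-adjacent and rendered disks stay disjoint as connected
components. Rendered disk areas match πr² within a perimeter-sized
rasterization tolerance.

What the generators do **not** emulate: probe-level microarray structure,
batch effects, spatially correlated expression noise, histological texture,
non-circular somata, staining gradients, or out-of-focus blur. Passing
tests therefore demonstrate correctness of the operators and calibration of
the statistics under idealized conditions, not performance on real slides
or arrays.

## Problem sizes used in validation

The acceptance-style suites run at desk scale, chosen once as the smallest
sizes at which the checked properties are statistically meaningful: 200
null cohorts of 5,000 genes × 10 regions for ANOVA/BH calibration; 100
cohorts of 51 individuals for breadth recovery (≈ 17 individuals per age
group); 350 planted markers for recovery; 50 disjoint and 20 overlapping
1,600 × 1,200 tiles for the segmentation oracle; 1,000 null comparisons of
30 vs 30 tiles with 1,000 shuffles for permutation calibration; 100 seeds
for age-model recovery and cell-type ranking; 20 paired seeds for the
discrimination comparison. `scripts/acceptance.py` recomputes the same
quantities at moderately smaller replicate counts and reports them with
the problem size used.

## Known limitations

- The specificity-score formula and threshold are an interpretive choice;
  derived marker lists are method-compatible with published lists, not
  identical to any.
- BH is applied per region; no cross-region joint correction is offered.
- The stepwise procedure inherits the usual selection-inference caveats:
  reported R² is in-sample and optimistic, and with permissive entry
  thresholds noise terms accumulate up to `max_terms`.
- Segmentation merges touching cells (no watershed splitting), so counts
  under heavy overlap are conservative; precision/recall ≥ 0.95 holds at
  ≤ 60 disks per 1,600 × 1,200 tile.
- Permutation tests treat tiles as exchangeable; with very few cases the
  effective sample size is overstated.
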