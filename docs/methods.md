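# Methods

This note documents the statistical models behind each `hscnet` module,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter
for reproducibility.

## Coordinates and genome model

All genomic coordinates are 0-based half-open (BED dialect), including
BEDPE loop anchors. `Genome` is an ordered map of chromosome names to
lengths; `random_placement` re-places length-matched intervals uniformly
at random, choosing the chromosome with probability proportional to its
length among chromosomes long enough to host the interval and the start
uniformly over the valid range. Placed intervals may overlap each other:
the permutation null is count- and length-matched only, with no
mappability constraint and no rejection sampling. The placement loop is
batched by interval width, so the random draws for a given seed depend
only on the multiset of widths, not on input order within a width class.

## Hurdle differential expression

Counts are normalized per cell to a fixed total (10,000 by default) and
transformed as log2(1 + x). For each gene the two conditions are
compared with a two-part likelihood-ratio statistic:

* a **detection** part — Bernoulli likelihood of the per-group detection
  rates against the pooled rate;
* a **continuous** part — equal-variance Gaussian likelihood of the
  nonzero log-normalized values with group means against a pooled mean,
  using maximum-likelihood variances, i.e. LR = m·log(RSS0/RSS1) over the
  m nonzero observations.

The sum is referred to a chi-square with 2 df. This follows the hurdle
principle of single-cell DE testing (detection and magnitude changes are
both informative) but deliberately omits the cellular-detection-rate
covariate and shrinkage used by fuller implementations; the simpler
2-df statistic is exactly checkable against brute-force likelihood
maximization, which the test suite does. Degenerate configurations — a
group with no detected cells, or zero within-group variance — contribute
zero to the continuous part, which is conservative.

Genes are tested when detected in ≥ 5% of either group's cells (the
threshold is an argument; 5% is a conventional single-cell detection
filter). P values are Bonferroni-adjusted over tested genes, matching
the convention of standard single-cell DE wrappers. log2FC is the
difference of group means of log2-normalized expression, control minus
perturbed, so the "down" network (higher in control, lost upon
perturbation) has positive log2FC. Network calls use log2FC > 0.05 and
adjusted P < 1e-20 by default — thresholds appropriate for the
thousands-of-cells regime, where even subtle coordinated shifts reach
extreme significance while label permutations yield nothing.

The permutation null (`permutation_de_null`) shuffles condition labels
across cells 100 times and records the number of network calls per
permutation; on exchangeable data this is zero throughout.

Pseudobulk concordance sums raw counts per condition, applies the same
CPM-log2 transform, and compares the pseudobulk log2FC against the
single-cell estimates by Spearman rank correlation restricted to tested
genes, with a one-sided cell-label-permutation P (default 1,000
permutations).

The per-cell signature score min–max scales each signature gene's
log-normalized expression to [0, 1] across cells and averages over the
set; a score above 0.5 calls the cell signature-high. The min–max
scaling is an interpretation choice — it makes the 0.5 cutoff meaningful
on any expression scale — and is the one deliberate free choice in this
module.

## Lineage enrichment z-score

For a gene set and a genes × cell-types profile matrix, the observed
statistic per cell type is the mean expression of the set; 1,000 random
same-size gene sets drawn uniformly without replacement from all
profiled genes give the permutation mean and s.d., and
z = (y_obs − mean)/sd, computed per cell type with the same draws scored
on every column. The permutation universe is all profiled genes; an
optional flag matches permuted genes on overall-expression decile as a
sensitivity analysis. When C(n_genes, set size) ≤ 10,000 the null is
enumerated exhaustively instead (exact z, verified against independent
enumeration in the tests). A zero permutation s.d. (e.g. a constant
matrix) returns z = 0 with a degeneracy flag rather than an error.
Adding a constant to a whole column shifts observed and permuted means
equally, so z is invariant — a useful sanity property for
normalization-shifted inputs.

## cisRE–gene linking

The catalog is the interval-set union of per-population peak sets, with
each element flagged by the populations whose peaks overlap it.
Candidate links are (cisRE, gene) pairs with the gene's TSS within
±500 kb of the cisRE midpoint; the link statistic is the Pearson
correlation of accessibility and expression across the shared ordered
population axis. Significance is empirical: the null distribution is
the same correlation computed for random *trans* pairs (cisRE and gene
on different chromosomes), the one-sided P is (1 + #null ≥ r)/(n_perm+1),
and q is the Benjamini–Hochberg adjustment. The stem-cell network keeps
links with q < 0.05 whose cisRE is open (accessibility > 0) in the HSC
column, scored as r × min–max-normalized HSC accessibility; the network
gene list is every gene with at least one retained link.

This scoring scheme — the distance window, the trans-pair null, and the
accessibility weighting — is a principled reconstruction from the
stated ingredients of multiomic cisRE–gene frameworks; every constant
is an argument, and the defaults (500 kb, q 0.05, 1,000 nulls) are
conventional for enhancer–gene linking.

Motif similarity between two position frequency matrices
column-normalizes both to frequencies and maximizes the Pearson
correlation of flattened overlapping columns over all offsets with at
least 5 shared columns, in both orientations (reverse complement =
reversed columns with complemented rows). The permutation null shuffles
the columns of the second motif. Uniform (zero-variance) motifs are
rejected explicitly.

## Footprint statistics

*Cleavage profiles* sum per-base cut counts over all sites of one motif
width (minus-strand windows reversed), normalized to a probability
vector over motif ± 250 bp. Sites truncated by a chromosome edge are
skipped and counted.

*Co-occurrence* defines a TF as a member of a cisRE when ≥ 1 of its
footprints overlaps it, and tests each TF pair with a two-sided
hypergeometric P computed by the method of small P values (sum of point
masses ≤ the observed mass, with a 1 + 1e-7 tolerance factor against
floating-point ties). This definition is exactly testable by
enumeration, which the suite does for N ≤ 12.

*Occupancy enrichment* counts cisREs overlapping ≥ 1 ChIP peak and
compares against 1,000 random re-placements of the length-matched peak
set; it reports the permutation z and the empirical
P = (1 + #perm ≥ obs)/(n_perm + 1), which is floored at 1/(n_perm+1) by
construction. A degenerate null (zero permutation s.d.) flags the
result and reports z = 0.

*Spacing* is the per-cisRE minimum edge-to-edge distance between two
TFs' footprints (overlap → 0), averaged over cisREs containing both.
Edge-to-edge with overlap→0 was chosen because the measured quantities
are nanometer-scale adjacency claims; center-to-center distances would
be inflated by motif widths.

*Signal contrast* runs a paired two-sided Wilcoxon signed-rank test of
each cell type's footprint signal against a reference cell type over
the shared footprints, and returns the matrix sorted by footprint
posterior descending for heatmap display. All-zero differences return
P = 1 rather than erroring.

## Contact maps, balancing, and APA

`ContactMap` is a per-chromosome symmetric dense matrix at fixed
resolution (25 kb default). Knight–Ruiz balancing uses the inner–outer
Newton iteration of the original algorithm on the submatrix of rows
with ≥ 10 nonzero entries (masked rows get NaN weights), producing
weights w with diag(w)·M·diag(w) having unit row sums; the row-sum
coefficient of variation after balancing is required to be < 1e-5 in
the acceptance checks and typically reaches 1e-8. If the KR iteration
stalls the implementation falls back to iterated proportional scaling
(logged); a fully-zero or non-balanceable matrix raises.

APA averages the balanced 21 × 21 submatrix (±10 bins = ±250 kb)
centered on each loop's anchor-bin pair, rows indexed by anchor-1
offsets (downstream increasing downward) and columns by anchor-2
offsets. Loops whose window crosses the matrix edge or the diagonal are
excluded with a logged count (exclusion, not padding, so the corner
statistic is never contaminated by the decay gradient). P2LL divides
the center pixel by the mean of the lower-left 6 × 6 corner (rows
15–20 × columns 0–5 of the aggregate; 36 bins). The per-pixel loop
stack is sorted before averaging so the aggregate is bit-identical
under any permutation of the loop list.

Two geometric facts worth knowing when reading P2LL values. On a
constant matrix P2LL is exactly 1. On a pure distance-decay matrix the
lower-left corner lies closer to the diagonal than the peak pixel, so
null P2LL is slightly *below* 1 by roughly (d − 15)/d for loop
separation d bins — the corner is deliberately the elevated-background
side of the window, which makes P2LL a conservative enrichment score.
For separations ≳ 2.5 Mb at 25 kb the effect is within ±0.2.

Loop classification marks a loop as a network loop when ≥ 1 anchor
overlaps a cisRE linked to a network gene, as CTCF-mediated when ≥ 1
anchor overlaps a CTCF footprint, and assigns to each loop the genes
whose spans lie entirely within the inter-anchor domain.

The corner contrast standardizes each condition's 36 corner values
against the mean and s.d. of its whole aggregate window and compares
the two sets with a two-sided t-test. Standardizing against the window
(rather than within the corner box itself) preserves shifts of the
corner relative to its own background — within-box standardization
would erase exactly the signal the contrast is meant to detect — while
still removing between-condition scale differences.

## Survival analyses

*Preranked GSEA* sorts the gene → metric ranking descending and walks
the classical weighted Kolmogorov–Smirnov running sum: hits increment
by |metric|^weight (normalized over hits), misses decrement by
1/(N − k); the enrichment score is the signed extremum. The null
permutes gene-set labels (random same-size sets, vectorized); NES
divides ES by the mean magnitude of same-sign null scores and the
one-sided P is computed within sign. A sample is called *enriched*
(NES > 0, P < 0.05), *depleted* (NES < 0, P < 0.05) or *neutral* —
the 0.05 cut is the operationalization of a categorical
enrichment/depletion call and is exposed.

The *per-sample ranking metric* is the sample's expression minus the
cohort mean per gene, on log2 scale, with genes mean-centered within
study first when a study label is supplied (so merged cohorts rank on
within-study deviations and study-level offsets cancel — verified by a
batch-offset invariance test). Per-sample GSEA constructions vary
across the literature; this difference-from-cohort-mean metric is the
package's default and alternatives (per-gene z-scores, within-sample
ranks) can be passed as precomputed metrics since `preranked_gsea`
accepts any gene → metric series.

*Youden thresholding* maximizes J = sensitivity + specificity − 1 over
the midpoints of sorted unique scores against the binary mortality
flag, breaking ties toward the lower threshold; it always equals an
exhaustive grid search (tested as such).

*Kaplan–Meier / log-rank*: product-limit curves per group via
lifelines; Mantel–Cox log-rank for two groups and its multivariate
generalization for more; with more than two ordered groups a log-rank
test for trend is computed from the summed per-event-time O−E vector
and covariance with integer scores 1..k (a score-invariance check under
score reversal is in the tests). Follow-up truncation is implemented as
administrative censoring at the cutoff day (event times beyond the
cutoff become censored at the cutoff), the standard treatment for
late-time data sparsity.

*Cox models* use lifelines' partial-likelihood fit with Efron tie
handling (the default of the standard survival stacks); HR = exp(coef)
with Wald 95% CI and P. Constant covariates and models with fewer
events than covariates are rejected up front; convergence failures
surface as errors with the underlying diagnostic. The marginal hazard
curve evaluates exp((g − ref)·β) over an exposure grid with a
delta-method Wald band, adding the exposure × age interaction term per
age when the design includes one; grid points outside the observed
exposure range trigger a warning, not an error.

*Cell-line stratification* splits lines at log2(RPKM + 1) ≥ 1
(boundary assigned high) and reports per-gene differential essentiality
as mean CERES(high) − mean CERES(low); negative values mean the gene is
more essential in high-expression lines.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); planted truths are
returned alongside the data and consumed only by tests and the
acceptance script, never by pipeline stages.

**Single-cell counts** are gamma-Poisson (negative binomial, dispersion
0.4) with LogNormal(0, 0.3) cell size factors and LogNormal(0, 1) gene
means floored at 0.3 counts/cell — a panel representing genes that
survive standard expression filtering, which is the population the DE
stage actually operates on. Extra dropout is applied with probability
logistic in the log expected count, midpoint 0.1 counts/cell and unit
slope, so zero inflation concentrates in low-expression genes at rates
in line with empirical droplet data (≈ 9% extra dropout at mean 1).
Planted DE genes (5% by default) are shifted ± 1 log2 unit in the
perturbed condition, half up and half down. Not emulated: batch
structure, cell-state heterogeneity, gene–gene correlation, ambient
RNA. Passing tests therefore demonstrate correct statistical behavior
under the hurdle model's own assumptions, not robustness to clustered
or batch-confounded designs.

**Lineage profiles**: gene baselines N(5, 1) with N(0, 0.5) noise per
cell type; the planted set adds a linear ramp of 2 log2 units from the
HSC column down to the most differentiated column. Real hematopoietic
compendia have correlated cell types and branch structure; the
generator's columns are exchangeable apart from the ramp.

**Multiome**: 18 populations; planted (peak, gene) pairs share one
latent factor per gene with loading √r (r = 0.8 default), giving
cross-population correlation ≈ r; unlinked peaks are placed near random
genes so they become candidate pairs but stay independent. Genes
alternate between two chromosomes so trans null pairs exist.

**Footprint landscape**: each TF occupies a cisRE with marginal
probability 0.3; planted pairs co-occur at a specified odds ratio via
the Plackett joint-Bernoulli construction (exact marginals and OR).
Cut-count tracks are Poisson(5)/bp with 5-fold protection inside
occupied motifs. Sequence content is not modeled.

**Contact maps**: expected counts c·max(d, 1)^(−1) from the diagonal
(c = 100), Poisson-sampled on the upper triangle and mirrored; loop
pixels are multiplied by (1 + strength) per condition. Anchors closer
than 21 bins to the diagonal are rejected. Not emulated: TADs,
compartments, translocation artifacts.

**Cohorts**: expression N(gene mean, 1) on log2 scale with the network
genes up-shifted by 1 log2 unit in enriched patients (≈ 40% of the
cohort) — a coherent program-level activation that is large relative to
unit gene noise, as network co-option in a malignancy would be.
Survival is exponential with the hazard multiplied by the true HR for
enriched patients; censoring is independent exponential calibrated so
the expected censored fraction equals `censor_rate`. The constant
baseline hazard makes closed-form sanity checks possible; real AML
hazards are far from constant, so absolute survival curves should not
be over-interpreted — the estimand exercised is the proportional-hazards
ratio, which the exponential model represents faithfully.

## Problem sizes used by the acceptance checks

The acceptance suite runs the permutation-null DE check at 1,000 +
1,000 cells × 2,000 genes with 100 permutations, recovery at 2,000 +
2,000 cells, occupancy calibration at 100 seeds × 1,000 permutations,
APA ordering at 100 seeds × 20 loops on 15-Mb maps, and the end-to-end
survival coverage at 200 replicates of 400-patient cohorts with
600-gene panels and 200-permutation per-sample GSEA. These sizes give
each binary check (e.g. "≥ 95 of 100 seeds") enough trials to be
meaningful while keeping the whole suite comfortably within an
interactive-session run time; the same statistical behavior holds at
larger sizes.

## Known limitations

* The hurdle test's chi-square reference is asymptotic; at very small
  group sizes (tens of cells) the continuous component can be
  conservative. The permutation null is the recommended companion check.
* cisRE–gene link scoring assumes one shared, ordered population axis;
  it does not model population relatedness (phylogenetic pseudo-
  replication across cell types will inflate correlations on real
  compendia).
* The trans-pair null for links requires input spanning ≥ 2 chromosomes.
* KR balancing operates per chromosome on dense matrices; genome-wide
  or very high-resolution maps need a sparse implementation.
* Per-sample GSEA calls use nominal P < 0.05 without cross-sample
  multiplicity control, matching the categorical-call design where the
  downstream survival model, not the call itself, carries inference.
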