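# Methods

`plexscreen` implements the computational arm of a multiplexed
pharmacotranscriptomics screen: cancer cells are treated in 96-well
plates (45 drugs spanning 13 mechanism-of-action classes plus DMSO
controls), labeled per well with a unique pair of hashtag-oligo (HTO)
antibody conjugates drawn from 8 row tags and 12 column tags, pooled for
single-cell RNA-seq, and analyzed from demultiplexing through
differential expression, pathway enrichment, signature scoring, drug
sensitivity scoring and perturbation-signature counting.  This note
records the models, the defaults and the deliberate design choices.

## Synthetic data generator

Because the package must be testable end-to-end without external
downloads, the generator in `plexscreen.synth` produces fully labeled
inputs with the statistical structure the analysis assumes.

**Plate design.** One 96-well plate per model (defaults: JHOS2, PDC2,
PDC3).  The 46 treatments (45 drugs + DMSO) are plated in duplicate
(92 wells) and the remaining 4 wells receive additional DMSO replicates,
giving 6 control wells per plate.  The published design states 96 wells
per plate and duplicate treatments but not the control-well count; the
46×2+4 split is this package's choice and is exposed through
`SimConfig`.

**Gene counts.** Per-well cell numbers are negative binomial around a
target of 130 cells/well (the real screen reported per-well medians of
122–140).  Gene baseline means are log-normal(μ=1.0, σ=1.2) over 2,000
genes, scaled by a per-cell log-normal library-size factor (σ=0.35),
yielding median library sizes near 11,000 UMIs — comfortably inside the
QC window.  Counts are NB with a shared size of 10 (dispersion 0.1).
Each MOA owns a disjoint module of 40 genes, half planted at log2FC +2
and half at −2 in every well treated with a drug of that MOA.  A
configurable fraction (1%) of genes are mitochondrial (`MT-` prefix);
their means are rescaled per cell so the mitochondrial fraction follows
a Beta distribution around a per-model mean (8/10/6% for
JHOS2/PDC2/PDC3), keeping most cells below the QC bounds while
exercising them.

**HTO counts.** The assigned row and column tags are NB with mean
μ_s = 200; all other tags are NB background with mean μ_b = 5 (shared
size 8), plus a Poisson(1) ambient add-on to every tag that mimics
variable surface-marker labeling.  5% of droplets are doublets (two
cells' gene and tag counts summed; their truth well is blanked when the
two cells came from different wells) and 5% are negatives (background
tags only).  Every droplet has exactly one truth record.

**Not emulated:** transcriptome-wide co-expression, batch effects,
cell-cycle structure, empty droplets and ambient mRNA.  Tests passing on
these data therefore demonstrate the correctness and calibration of the
algorithms under the stated model, not robustness to every artifact of
real scRNA-seq.

**Dose-response truths** are rising four-parameter logistic curves with
bottom U(0,5)%, top U(30,100)%, log10 EC50 uniform inside the tested
window and Hill slope U(0.7,2).  Responses add Gaussian noise (σ=5%)
and are clipped to [−10, 110].  The **perturbation-signature corpus**
assigns each synthetic experiment an MOA/tissue/timepoint and emits up
and down gene sets of exactly `set_size` genes (default 250); planted
genes enter the up sets of matching-MOA experiments with a stated
probability.

## Demultiplexing

Row and column families are classified completely independently.
Within a family, counts are CLR-transformed per cell across the family's
tags (ln(x+1) minus the mean of ln(x+1); the compositional margin — each
cell's CLR row sums to zero).  k-means with k = n_tags + 1 clusters the
CLR matrix; for each tag the cluster with the lowest mean CLR of that
tag is its background (ties broken toward the larger cluster; clusters
are accreted in ascending order until the background holds at least
`min_background` cells).  A negative binomial is fitted to the
background's raw counts by maximum likelihood (method-of-moments start;
Poisson fallback with a warning when the sample is under-dispersed), and
the positivity threshold is the fitted distribution's `q` = 0.99
quantile.  A cell is positive for a tag when its raw count strictly
exceeds the threshold; 0/1/≥2 positive tags give negative/singlet/
doublet.  Cells that are singlets in both families and whose tag pair
exists in the plate map are retained with that well's treatment; others
are discarded with a reason (`row_not_singlet`, `col_not_singlet`,
`pair_not_in_map`).  Raising `q` can only raise thresholds, so the
number of positive calls is monotone non-increasing in `q`.

On default synthetic plates (~12,000 droplets) this recovers >99% of
true singlets into their true well with no wrong-well assignments
observed, and rejects essentially all negatives and >99% of doublets.

## QC, clustering, markers

QC keeps a cell iff `umi_min < total UMIs < umi_max` and mitochondrial
percentage `< mito_pct_max[model]` — all bounds strict (defaults
2,500/80,000 and 25/30/20% for JHOS2/PDC2/PDC3).  Expression is
log-normalized, ln(1 + count/library × 10⁴); heavier variance
stabilization and batch correction are intentionally out of scope (the
synthetic data carry no batch structure).  Clustering reduces to 50
truncated-SVD components when needed, builds a k-nearest-neighbor graph
(k = 15), converts it to a shared-nearest-neighbor graph with Jaccard
edge weights pruned below 1/15, and partitions it with the Leiden
algorithm (RB-configuration quality, resolution 0.3, seeded).  Labels
are relabeled contiguously from 1 by decreasing size.  Markers are
one-vs-rest Wilcoxon rank-sum tests per gene (mid-ranks; scipy's policy
of exact enumeration for small tie-free groups and the
continuity-corrected normal approximation otherwise), Bonferroni
adjusted over all features, with log2FC of cluster-vs-rest mean
expression under a pseudocount of 1.

## Subsample-pseudobulk differential expression

Each (model, treatment) group is shuffled (Fisher–Yates, with an
independent stream per group: the stage seed XOR a CRC32 hash of the
group key) and cut into chunks of 10 cells; a final chunk survives only
with ≥5 cells, and a group enters the analysis only with ≥2 subsets.
Consequently groups of ≤14 cells are excluded — the boundary is proved
by enumeration in the tests.  Subset columns are raw-count sums.

Genes with average log2 CPM < 1 are removed, computed with a
library-size-scaled prior count of 2 (prior_j = 2·lib_j/mean(lib);
log2((y+prior_j)/(lib_j+2·prior_j)·10⁶) averaged over the compared
subsets).  TMM factors use the column whose upper-quartile CPM is
closest to the mean upper quartile as reference, doubly trim M-values
(30%) and A-values (5%) by rank, weight by the usual asymptotic
(delta-method) variances, and are rescaled to geometric mean 1.

The test itself is a reduced but faithful NB quasi-likelihood pipeline.
Per gene, group means are fitted by vectorized Fisher scoring on the log
scale with offsets log(lib × TMM factor).  Dispersions are estimated by
adjusted profile likelihood (Cox–Reid 0.5·log det(XᵀWX) correction) on a
30-point log-spaced grid (10⁻⁴–2); the per-gene APL curves are smoothed
along the abundance ordering (moving average over ~10% of genes) to give
a trend, and each gene maximizes APL_g + 10 × (local trend APL) — a
weighted-likelihood empirical-Bayes shrinkage.  With the shrunk
dispersion, full (two means) and reduced (one mean) models give
deviances; the per-gene quasi-dispersion s² = deviance/df is moderated
with a scaled inverse-chi-square prior fitted by moment matching on
log s² (trigamma inversion), and the statistic
F = (D_reduced − D_full)/s²_posterior is referred to F(1, df_prior +
df_residual).  P-values are Benjamini–Hochberg adjusted.  Full Cox–Reid
multi-coefficient adjustment and robustified priors are deliberately
omitted; correctness is assessed by calibration, not by coefficient
equality with any external package.  On the default simulation (2,000
genes, 4 subsets per arm, NB dispersion 0.05) the null type-I error at
α = 0.05 is ≈0.044, planted log2FC = 2 is recovered with median error
<0.1, and the empirical FDR among discoveries at FDR < 0.01 is ≈0.01.

DEG counting keeps protein-coding genes with FDR < 0.01 and
|log2FC| > 0.5 (strict); MOA unions use the looser |log2FC| > 0.25 for
the ORA input.  ORA is an upper-tail hypergeometric test of the query
against each set intersected with the background (all genes passing the
low-expression filter in the compared subsets — the package's choice,
since the original analysis delegated this to a web tool), BH-adjusted,
kept at FDR < 0.05, optionally intersected with a cancer-pathway
allow-list, deduplicated by term name (most significant instance kept)
and capped at the 20 most significant rows.

## Signature scoring

Gene sets are size-filtered to [10, 500] (inclusive).  The cluster
profile is the per-cluster mean expression of the union of each
cluster's top-50 up- and top-50 downregulated markers (by log2FC).  A
set's score in a cluster is the mean profile value over the set ∩ panel
minus the mean over the whole panel.  This is deliberately the
marker-profile procedure, not a canonical per-sample KS-style
enrichment statistic.  Significance bootstraps genes within the panel
(the resampling unit is not dictated by the original description;
resampling cluster cells is the obvious alternative and the gene-level
choice is exposed in the API surface): B = 1,000 draws of |set ∩ panel|
genes with replacement, p = (1 + #{|null| ≥ |observed|})/(B + 1) —
never exactly zero, and sub-uniform under the null by construction.
Selection keeps the ceil(5%) of sets with the largest coefficient of
variation across clusters (sd/|mean|; a zero mean maps to +∞ and ranks
first, flagged to the caller by its infinite CV).

## Drug sensitivity scores

Five-point % inhibition curves over a 10,000-fold concentration range
are fitted with a bounded 4PL (bottom ∈ [−10, 30], top ∈ [0, 110],
log10 EC50 within the tested grid ± 1, Hill slope ∈ [0.1, 10]) by
deterministic multi-start least squares (starts at each tested
concentration × slopes {0.5, 1, 2}); identical responses yield a flat
degenerate fit with slope 0 and a warning.  The DSS integrates
max(0, min(y, 100) − t) over log10 concentration (Simpson's rule,
2,049 points) and normalizes by (100 − t)·(x_max − x_min), with
activity threshold t = 10%.  The score is bounded in [0, 100], monotone
in the curve, and depends only on the log-range (unit-invariant).  The
screen-wide sensitivity cutoff is recomputed as the 75th percentile of
the DSS distribution (linear interpolation, h = (n−1)p + 1) — it is
data-dependent, never hard-coded.

The group comparison uses an exact two-sided Wilcoxon rank-sum test:
mid-ranks, and for total n ≤ 25 the full null (every C(n, n_a) rank
assignment equiprobable) evaluated by dynamic programming over doubled
ranks (exact also under ties); beyond 25, the tie- and
continuity-corrected normal approximation.  Two groups of sizes 3 and 5
in complete separation give p = 2/56 = 0.0357… → 0.036 at three
decimals.

## Perturbation-signature counting

Corpus experiments are filtered by MOA (default {AKT inhibitor, PI3K
inhibitor}; exact label match after case-folding, not substring),
tissue (default {ovary, breast}) and timepoint (default
{24, 48, 72, 96, 120} h, numeric match).  For each signature gene the
number of filtered experiments whose up (down) set contains it is
counted; a gene appearing in both sets of one experiment is counted
once per direction.  Output is sorted by up_count − down_count
(waterfall order); Σ_genes up_count equals Σ_experiments
|up set ∩ signature| by construction.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
as the package's own test design: one synthetic plate (~12,000
droplets, 2,000 genes) for demultiplexing recovery; 2,000-gene, 4
subsets-per-arm simulations for DGE calibration; universes ≤30 for the
exact enumeration oracles; sizes 1–1,000 for the partition boundary.
Corpus-scale quantities that depend on external data (the 1.4M-
experiment corpus, the screen's DSS cutoff value of any particular
dataset) are recomputed from whatever data are supplied, never assumed.

## Known limitations

- The demultiplexer assumes two well-separated count populations per
  tag; heavy ambient contamination or strongly varying signal across
  wells would require per-well mixture modeling.
- The QL pipeline supports exactly one treatment-vs-control contrast;
  multi-factor designs and random effects are out of scope.
- The signature score operates on marker-average profiles and is not
  comparable to per-sample enrichment scores from other tools.
- 4PL fitting with 5 points cannot resolve curves whose EC50 lies far
  outside the tested range; the bounded fit then returns a boundary
  estimate and the DSS degrades gracefully toward 0 or the plateau
  value.
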