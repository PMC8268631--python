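# Methods

`cartograph` implements self-organizing-map (SOM) "portrayal" of paired
bulk gene-expression and promoter-methylation cohorts, together with the
downstream machinery that turns trained maps into biology: spot modules,
gene-set scores, survival and phenotype association maps, and a network
coupling expression modules to methylation modules.  This note records
the models, the parameters that matter, the numerical conventions, and
the limits of what the synthetic test-bench demonstrates.

## Preprocessing

Expression values enter on log10 scale (a `log10(x + 1)` transform is
available for raw non-negative intensities).  Columns are quantile
normalized: every sample receives the distribution of across-sample mean
order statistics, with ties mapped to the mean of their tied reference
slots, so within-column ranks are exactly preserved and the operation is
idempotent.  Array-specific calibration and background-noise correction
are upstream responsibilities and not implemented here.

CpG beta values (fractional methylation in [0, 1]) are aggregated
gene-centrically: the promoter window spans 2 kb upstream to 200 bp
downstream of the TSS, strand-relative ("upstream" = 5'), as a closed
1-based interval, and the gene's promoter beta is the plain mean over
CpGs inside the window.  CpGs missing in a sample are dropped from that
sample's mean (pairwise deletion).  Genes with no CpG in the window are
dropped and reported.  Genes on chrX/chrY (any common spelling) are
excluded before training to avoid sex bias in the maps.  Gene rows are
mean-centered before SOM training so portraits read as up/down
regulation relative to each gene's cohort mean.

## Batch SOM

Genes are points in sample space; the map holds `grid_k**2` metagene
prototypes.  One epoch (i) assigns every gene to its Euclidean
best-matching unit (BMU; ties broken by lowest unit index) and (ii)
replaces each prototype by the Gaussian-neighborhood-weighted mean of
all gene profiles, with kernel `exp(-d^2 / 2r^2)` over squared grid
distance `d^2`.  The radius anneals linearly from `grid_k/2` to 0.5 over
the first 75% of the epochs (default 40) and is then frozen, so the
final quarter behaves like a softly-smoothed k-means whose quantization
error (mean squared gene-to-BMU distance, recorded per epoch) settles
monotonically.  Batch updates are order-free, making training
deterministic given the matrix and parameters.

Initialization is linear on the first two principal axes of the gene
cloud (sign-fixed SVD, no randomness), with seeded random gene-sampling
as a fallback.  Empty units keep their prototype; they host no genes but
still interpolate the map surface.  Grid defaults: 50x50 for expression,
30x30 for (less diverse) methylation landscapes.  "Zoom-in" maps are
ordinary retraining on a sample subset — there is no separate code path.

A known behaviour of this geometry: with several equally strong,
mutually orthogonal gene modules, the large-radius phase approximates a
two-dimensional principal surface and tends to stack module clusters
into the map corners, so two modules can occupy adjacent blobs.  This
motivates the group-resolved spot segmentation below.

## Spots

The overexpression summary map is the pixel-wise maximum over group-mean
portraits.  The segmentation primitive thresholds a portrait at the
nearest-rank q-quantile of its unit values (strictly above; q = 0.98 by
default), takes 8-connected components, drops components below
`min_size` = 3 units, and labels spots A, B, ... by descending peak.
Nearest-rank quantiles (no interpolation) are used everywhere for exact
reproducibility.  Underexpression spots are available by negation.

Because the summary max can bridge regions upregulated in *different*
groups that happen to lie adjacently (see above), the pipeline's default
segmentation is group-resolved (`detect_group_spots`): the threshold is
computed once on the summary map but applied to each group-mean portrait
separately, and components from different groups are merged when they
share units.  With subtype-specific modules this separates adjacent
modules cleanly; on the synthetic bench it recovers 6/6 planted modules
on ten consecutive seeds where summary-map segmentation recovered as few
as 2.  Note that q must leave a foreground budget comfortably above the
expected total module area (at the very least `n_modules * min_size`
units), otherwise the threshold cuts into the signal plateau and
group-level noise fragments modules below `min_size`.  The bench uses
0.98 on the 50x50 expression map (50-unit budget for ~42 elevated
units), 0.97 on the 30x30 methylation map (27 for ~21), and small
demonstration grids use lower q still (0.90 at 14x14).

A spot is *called* in a sample when the sample's mean portrait value
over the spot's units strictly exceeds the 0.90 nearest-rank quantile of
that sample's own unit values — a rank rule invariant to per-sample
shifts.  Implication edges join spots whose directional co-occurrence
confidences `P(B|A)` and `P(A|B)` both exceed 0.5 within a group.
Cross-map gene mapping reports per-unit density and a dispersion score:
Shannon entropy of the gene distribution over target-spot bins plus one
background bin, normalized by log(bins).  Dispersion separates "one
module, one counterpart spot" (0) from spreading across several spots
(→1); it cannot distinguish a set confined to one spot from a set
confined entirely to the background bin — both are maximally
concentrated in one bin.

## Gene sets

The GSZ score standardizes a set's summed value in one sample against
exact finite-population sampling moments: for a sample with N gene
values (mean mu, population variance sigma^2) and a set of size n,

    GSZ = (sum_set - n*mu) / sqrt(n * sigma^2 * (N-n)/(N-1)),

i.e. a z-score under hypergeometric (without-replacement) sampling of n
genes.  Random sets therefore have mean 0 and variance 1 by
construction; a zero-variance sample scores 0.  This set-sum z variant
contains no between-gene variance shrinkage terms; it is exactly
checkable by subset enumeration.  Set-overlap enrichment uses the
one-sided hypergeometric upper tail (Fisher's test direction of
enrichment; two-sided available), with a 0.5 Haldane correction on the
odds ratio when a cell is zero.  The universe is the gene set shared by
the two maps under comparison.

## Phenotype maps

The prognostic map fits, per unit, a univariate Cox proportional-hazards
model with the unit's standardized metagene value as a continuous
covariate, so the stored log HR is per SD; dichotomizing at an arbitrary
cut is avoided.  The fitter is a Newton–Raphson maximizer of the partial
likelihood with Breslow tie handling (Efron available), converged at
|score| < 1e-8 within 50 iterations.  Units with constant metagene,
fewer than 2 events, non-convergence, or a monotone likelihood (|beta| >
10, complete separation) are flagged invalid, never zeroed silently.
Kaplan–Meier curves and the multi-sample log-rank test are delegated to
lifelines.  Continuous covariates (age, telomere-length ratio) map to
per-unit Pearson correlations.  The female difference score selects, per
unit, samples with portrait value strictly above the nearest-rank 0.75
quantile and reports `100 * (pct_female_selected - pct_female_all) /
pct_female_all` ("percent-of-percent", a relative deviation — the
normalization chosen among the plausible readings).  No multiplicity
correction is applied to the maps; they are descriptive, and z-values
are exported for downstream FDR.

## Expression–methylation integration

The covariance map colors each unit of a host map by the mean, over
genes assigned to the unit, of the population (1/n) covariance between
the gene's expression and promoter beta across shared samples.  The
per-gene values are geometry-free; only the aggregation differs between
the E- and M-map.  The E–M network joins expression and methylation
spots with Fisher overlap p < 1e-3 *and* anti-correlated per-sample spot
profiles (Pearson r < 0; any negative correlation qualifies, spot-mean
metagene profiles being the correlated objects).  Connected components
of the network are the cohort's combined regulatory modes.  Sample
similarity is Pearson correlation between metagene vectors, ordered by
average-linkage clustering of 1 − r, with a top-3-neighbor net.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-subtype
glioma-like cohort at bulk resolution.  Defaults (the bench's study
conditions): 5,000 genes × 120 samples, 6 subtypes cycling over samples,
6 disjoint modules of 40 genes, module m activated by 1.0 log10 unit in
subtype m (block model: a sample's module activity is its subtype's
activation entry), gene-level Gaussian noise SD 0.25 log10 units.  Half
the modules are methylation-coupled: each of their genes carries
`cpgs_per_gene` = 5 CpGs placed uniformly in the promoter window, with
per-CpG beta = 0.5 − 0.3·activity + N(0, 0.05), clamped to [0, 1]
(clamping after noise, since beta is a fraction); uncoupled genes get
baseline + noise.  Gene annotation cycles autosomes chr1..chr22, with 2%
of background genes placed on chrX/chrY to exercise the sex filter.
Survival is exponential with log-hazard linear in module activity
(default coefficients 0: survival independent of the transcriptome,
the correct null for calibration checks), baseline rate set so median
survival is 5 time units, and uniform censoring whose horizon is solved
numerically for an expected 20% censored fraction.  Age, sex and
telomere-length ratio are independent covariates.

What the bench does **not** emulate: probe-level intensities, copy-number
dose effects, cell-type mixtures, correlated noise between genes,
overlapping modules, graded (non-block) activation, or methylation
changes unaccompanied by expression changes.  Passing recovery tests
therefore demonstrates that the machinery recovers block-structured
planted signal at realistic noise — not that it resolves the subtler
continuous structure of real cohorts.

## Problem sizes and numerical choices

The test-bench trains 50×50 expression and 30×30 methylation maps on the
default cohort (about 20 s and 5 s respectively per seed on one CPU) and
repeats the recovery and network analyses over ten seeds; survival
calibration uses 100 replicates at n = 500 and the score-null check uses
10,000 draws.  Tolerances: exact oracles (GSZ, Fisher, quantile
normalization) to 1e-9..1e-12; Cox Newton vs. grid search to 1e-6;
stochastic calibration checks use 3-sigma binomial bands or documented
intervals.  All quantiles are nearest-rank; all variances in descriptive
statistics are population (1/n) unless noted; BMU ties break to the
lowest unit index; TSV outputs use a fixed "%.10g" float format so
reruns are byte-identical.

## Known limitations

- Segmentation is threshold-plus-connectivity; watershed-style splitting
  of genuinely merged regions is not attempted (group resolution covers
  the common case of group-specific modules).
- The per-unit Cox fits are univariate and unadjusted; confounding
  between map regions and clinical covariates is not modelled.
- The dispersion statistic's single background bin hides spread that
  stays outside all spots.
- Real-data idiosyncrasies (batch effects, probe cross-hybridization,
  missing-not-at-random betas) are out of scope upstream of the matrix
  interfaces.
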