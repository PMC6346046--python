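# Methods

This note documents the statistical models, the defaults and why they are
set where they are, what the synthetic data do and do not emulate, and the
numerical choices a reader would need to reproduce results exactly.

## Count model and normalization

Counts are modelled as negative binomial with mean μ and dispersion α,
variance μ + αμ² (the NB2 parameterisation standard for RNA-seq). Size
factors use the median-of-ratios convention: for genes observed and
positive in every sample, factor_j = median_g (count_gj / geometric
mean_g), rescaled to geometric mean 1 so the normalized scale is anchored.
If no gene is positive everywhere the estimator refuses rather than
silently switching reference (the error suggests a pseudo-reference
fallback).

RPKM is count / ((length/10³)·(mapped_total/10⁶)); when per-library mapped
totals are unavailable (they cannot be recovered from a count table) the
column sums stand in, and the run report records that.

The variance stabilizer is log2(count/size_factor + 1). It is deliberately
*not* a re-implementation of a dispersion-trend-based transform: every
downstream consumer (standardization, correlation networks, PCA) depends
only on a monotone, roughly variance-flattened scale, and the simple form
is exactly reproducible. Per-gene standardization uses mean 0 / sd 1 with
denominator n−1; with three replicates per time point the ddof convention
is material, so it is fixed here.

## Sample-level QC

PCA is computed on the centered sample × gene matrix. The "time points
separate" claim is operationalized as the silhouette coefficient of
time-point labels in PC1–2 score space, with "separated" iff silhouette
> 0.25 (a conventional weak-structure threshold; configurable). Covariate
screening tests each component's scores against the covariate with a
Pearson test and BH-adjusts across components. The marker report averages
RPKM per time point per marker and calls the capture "enriched" when
target-population markers exceed off-target markers by 10× on mean RPKM.

Note an honest artefact of the synthetic fixture: with 85 % of genes pure
noise and strong module-level latent factors, PC1–2 of the default
synthetic study are dominated by module fluctuations, not time, so the
separation verdict is typically negative there. The operation itself is
validated on limit cases (two groups offset by a large constant →
silhouette ≈ 1) and against a permuted-label baseline (mean silhouette
≈ 0). Real data whose dominant variance axis is developmental will
separate; the synthetic default does not claim to reproduce that.

## Time-course differential expression

Per gene, the full model gives each time point its own mean on a log link
with per-sample offsets log(size factor); the reduced model has one mean.
With dispersion α held fixed, the group-mean MLE solves
Σ_j (y_j − s_j m)/(1 + α s_j m) = 0, done by Newton steps on log m
(expected information Σ μ_j/(1+αμ_j), step clipped to ±5, tolerance 1e−10,
max 100 iterations; all-zero groups get m = 0). The LRT statistic
2(ℓ_full − ℓ_red) is referred to chi-square with T−1 degrees of freedom;
BH q-values across tested genes. Time is an unordered factor in the GLM;
the ordinal ranks are used only afterwards, to assign each significant
gene a trend sign by the Spearman correlation of its fitted time-point
means with the ranks (zero or undefined correlation → excluded with a
warning). All-zero genes are excluded and counted.

Dispersion is estimated by method of moments within time points:
Var(count/sf) ≈ mean·E[1/sf] + α·mean², pooled across time points with
weights (replicates − 1). Two small-sample details matter at three
replicates:

- the denominator uses the unbiased moment estimate of μ², m̄² − v/J
  (capped at halving), because m̄² alone carries the sample mean's own
  variance and biases α down by ~5 %, which visibly inflates the LRT's
  type-I error;
- the per-gene estimate is then shrunk toward a mean–dispersion trend
  α(m) = a₀ + a₁/m (non-negative least squares on 1 %-winsorised raw
  estimates), with weight 0.25 on the per-gene value. Heavier weight on
  the noisy per-gene estimate is anti-conservative: plugging a noisy α
  into the LRT inflates its size (the effect is convex in the estimation
  error). With weight 0.25 the simulated size of the test at the study
  design (2000 genes, α = 0.1, 5×3) stays within 0.04–0.06 across seeds
  while per-gene signal is retained for genuinely outlying genes.

Estimates are floored at 1e−8. No outlier replacement, independent
filtering or fold-change shrinkage is attempted.

## Co-expression network

Pearson correlation (pairwise-complete when values are missing) feeds a
signed adjacency a = ((1+r)/2)^β, which maps r = −1 to 0 — anti-correlated
genes are *not* connected, matching the "signed" network convention.
Genes with more than 50 % missing values or zero variance are removed
first. The soft-threshold scan reports, per candidate β, the mean
connectivity and the signed scale-free fit: R² of log₁₀ p(k) vs log₁₀ k
over 10 equal-width connectivity bins, negated if the slope is positive.
The chosen β is the smallest candidate with R² ≥ 0.8, else the argmax; a
pinned power overrides the scan (reproduction runs pin the published
values, 3 and 4).

Topological overlap is TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij) with unit diagonal; 1 − TOM is clustered by average linkage. The
tree is cut statically at a quantile of its merge heights (default 0.15)
and clusters below the minimum size (30) are left unassigned. The quantile
cut replaces dynamic tree cut; its default sits just above the fraction of
merges that build coherent modules when a minority of genes is modular
(planted-module fixtures here have 15 % modular genes). Analyses where
most genes are modular need a correspondingly higher quantile — the
parameter is a fraction of the tree, not a height. Module labels are
assigned by decreasing size with lexicographic tie-break, so they are
invariant to gene order.

Eigengenes are the first right singular vector of the standardized module
sub-matrix, sign-oriented to correlate positively with the module's mean
profile (otherwise pos/neg temporal labels would be arbitrary). Modules
whose eigengene dissimilarity (1 − r) links below 0.5 under average
linkage are merged, eigengenes recomputed, and the pass repeated to a
fixed point — so merging is idempotent by construction. kME is the Pearson
correlation of each gene with each eigengene; "core" members of a module
have kME > 0.8. Modules are classed pos/neg by the Pearson correlation of
their eigengene with time ranks at |r| > 0.5 and p < 0.05. Cross-tissue
coherence of a gene set is the variance-explained share of PC1 of those
genes' standardized profiles in the other tissue's matrix (missing when
fewer than two genes are present).

## Enrichment with length-bias correction

Backgrounds restrict to protein-coding genes and either all expressed
non-zero-variance genes or, for cross-species disease lists, those with
1:1 orthologs; the run report records the mode. The central test is the
hypergeometric upper tail (Fisher's exact, over-representation only). The
length correction fits a probability weighting function — a monotone
non-decreasing regression of cluster membership on gene length — by
isotonic regression on equal-occupancy length bins (~50 genes/bin; binning
keeps the boundary estimates consistent, where a raw per-gene isotonic fit
collapses to the extreme genes' 0/1 values), clipped to [1e−6, 1−1e−6].
The PWF is reduced to one odds parameter, mean weight inside the tested
set over mean weight outside, and the overlap is referred to the Wallenius
noncentral hypergeometric law with that odds (scipy's implementation of
Fog's methods). At odds exactly 1 the law *is* the central hypergeometric
and the code routes there, so the equal-weight corrected test reproduces
Fisher's p to machine precision. BH families are one family per set
collection per cluster. Depletion claims are handled by the dedicated
overlap test, not by lower tails here.

## The ratio-of-odds-ratios permutation test

The four observed tables (tissue × ID stratum) are built as
(|set∩cluster|, |set∖cluster|; |cluster∖set|, rest) over an explicit
universe. Haldane's correction adds 0.5 to every cell of a table that
contains a zero — only then, and never twice (a corrected flag prevents
double correction). OR = ad/bc; per tissue ROR = OR_ID/OR_ID-free;
Δ = |log₁₀ ROR_A − log₁₀ ROR_B|.

Each permutation redraws all four tables independently from the uniform
(central) distribution of tables with the observed margins fixed. The r×c
sampler fills row i with a multivariate hypergeometric draw of the row
total from the still-unallocated column margins — the sequential
conditional decomposition of the fixed-margins law; for 2×2 this is a
single hypergeometric draw, vectorised across permutations. Haldane is
applied per drawn table only when that draw contains a zero. The empirical
p-value is the add-one convention (#{Δ* ≥ Δ_obs}+1)/(B+1), which cannot
return zero; B defaults to 10⁵ (the published analysis used 10⁸; B is a
config knob and is recorded with the seed in every result). P-values from
the stratified runs (syndromic-only; categories 1–4) are BH-adjusted
across strata. Degenerate margins (an empty row or column) are an error
naming the table, since the conditional law would be a point mass.

The cross-cluster depletion test is a plain hypergeometric tail on the
overlap of two gene sets in an explicit universe, with the tail
(less/greater/two-sided) an explicit argument — published overlap p-values
are sensitive to the universe convention, so the operation refuses to
guess.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study *design*: 5 time points (P0–P21) × 3
replicates; NB counts with α = 0.1; baseline log2-means N(6, 1.5);
log-normal gene lengths (median 2 kb, σ = 1); log-normal depth factors
(σ = 0.2) so size-factor estimation is non-trivial; planted modules of 50
genes with log-linear trajectories (default span 3 log2 units across the
course); and disease lists sized after the published composition — an
ASD-like list of 182 annotated genes (90 ID-yes / 92 ID-no; syndromic
subset 30 / 11) with cross-tissue composition odds 8 vs 0.1, a neutral
schizophrenia-like list, and an ataxia-like list with 5× planted module
enrichment.

Two modelling points deserve emphasis. First, module members share a
latent per-sample log2 fluctuation (default sd 0.75): without it, two
modules with the same trajectory direction are *identical* in expectation
and no co-expression method could separate them — a module is a
correlation block, not just a shared mean curve. Second, tissue module B
is temporally flat but coherent (its own latent sd 1.3, matching the
trending modules' total coherence), because the contrast the ROR test
quantifies is between a development-correlated cluster and a cluster
without positive developmental regulation.

Not emulated: read-level artefacts, batch effects beyond depth, missing
values (supported by the data model, not planted by default), ortholog
many-to-many structure (the synthetic annotation is all 1:1), and any
realistic gene-length/expression dependence unless `length_de_factor` is
set. Passing tests therefore demonstrate correctness of the machinery and
its calibration under the stated model, not robustness to artefacts the
generator does not produce.

All randomness flows through numpy PCG64 generators seeded from the
configuration (child streams via SeedSequence), so every output is
bit-reproducible per seed and platform-stable at the level of drawn
integers.

## Problem sizes used in validation

The validation suite runs the module-recovery study at 1000 genes
(3×50-gene modules), the DE calibration and power studies at 2000 genes,
permutation calibration at 500 replicates × B = 2000, planted-bias
detection at 50 replicates × B = 10⁴, and sampler goodness-of-fit at 10⁵
draws — sizes at which the Monte-Carlo error of each check is comfortably
below its acceptance band.

## Known limitations

- The static quantile cut is not dynamic tree cut; module *counts* on real
  data will differ from the published 17/12, which depended on unstated
  package defaults. Module counts are therefore not a validation surface.
- The LRT's chi-square reference is asymptotic; at 15 samples its size is
  ≈ 0.05 ± 0.01 depending on the realized mean spectrum, which is why the
  dispersion estimator's small-sample behaviour gets first-class
  attention above.
- The Wallenius reduction uses the two-group mean-weight approximation
  (as the cited correction tool does), not per-gene exact biased-urn
  computation; the Monte-Carlo oracle test bounds the approximation error
  at the scales used.
- Empirical p-values are bounded below by 1/(B+1); claims beyond that
  resolution require raising B.
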