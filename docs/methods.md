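# Methods

This note documents the models, estimators and numerical choices behind
phenomap, and what the synthetic benchmarks do and do not establish.

## Growth-curve feature extraction

A well's OD series (20-min sampling over 72 h in the emulated design) is
reduced to lag, doubling time and efficiency.

* **Baseline.** The inoculum level is the median OD of the first 2 h
  (configurable quantile). The median, rather than a low quantile, is used
  because measurement noise around the pre-growth plateau drags a 5%
  quantile toward zero, which destroys the lag tangent-intercept (ln of a
  near-zero baseline). The baseline is *not* subtracted before the log
  transform: a microcultivation baseline contains the inoculum, and
  computing slopes of ln(OD − baseline) makes the exponential-phase
  log-slope r·N/(N−N₀), which diverges at the start of growth and biases
  the rate upward without bound. Input OD is therefore treated as
  blank-corrected density; any residual instrument blank is removed with the
  separate `blank` parameter (default 0).
* **Rate.** Sliding-window OLS (default 5 samples ≈ 80 min) on the log of
  the moving-average-smoothed OD. Candidate windows must sit wholly above
  `baseline + max(0.25·baseline, 5·noisê)` where noisê is the SD of the
  first 2 h — pre-growth noise cannot masquerade as exponential growth. The
  steepest window is selected by a lower confidence bound (slope − 2·SE);
  the selected window's slope μ gives the doubling time ln 2/μ. The LCB
  selection leaves noiseless curves untouched but stops max-over-windows
  from chasing noise excursions.
* **Lag.** The tangent through the selected window intersected with
  ln(baseline).
* **Efficiency.** max(smoothed OD) − baseline.
* **Degenerate wells.** A total density change below 0.05 OD flags
  `no_growth`: rate and lag are reported missing rather than as extreme
  numbers that would contaminate downstream statistics. Negative tangent
  intercepts clip to 0 with a `lag_clipped` flag.

Validation: on a noiseless 100-curve grid (lag 2–20 h, doubling time
1.5–12 h, efficiency 0.2–1.2 OD) extraction recovers all three parameters
within 3.3% (the acceptance suite asserts 5%). The round trip is only
meaningful for curves that reach stationary phase, so the benchmark grid
uses a per-curve duration `lag + Td·(log₂(K/N₀) + 10)`; at 72 h a
12-h-doubling, 20-h-lag culture physically cannot express a 1.2-OD
efficiency. With realistic noise (OD sd 0.003, inoculum 0.05) component
errors are ~5–7% median — the same order as the few-percent-to-11.6%
replicate CVs typical of this assay class.

## Relative traits

Per run, value = log₂(reference-run-mean / strain value) for lag and rate;
for efficiency the ratio is inverted so positive always means superior
proliferation. Runs are averaged after the log transform
(`NormalizationPolicy.MEAN_OF_LOG_RATIOS`); averaging ratios before a single
log is available behind the policy switch, and the two coincide when runs
agree. Nonpositive raw values become missing with a `nonpositive` flag; a
missing run-matched reference is an error naming the run. Replicates
(n = 2 in the emulated design) are averaged after normalization;
replicate-level values feed only the CV report (CV = sd/mean on the raw
scale per strain × trait cell).

## Trait statistics

* **Group tests** are two-tailed pooled-variance t-tests per trait,
  Bonferroni-corrected over the *tested* traits (≥ 2 values per group);
  Welch's form is available behind `equal_var=False`. Degenerate traits
  (all values equal) give p = 1. Group comparisons act on per-strain values
  grouped by clade/species; testing group means instead is a documented
  alternative the caller can implement by collapsing the matrix first.
* **Specific traits**: each group vs the union of all others,
  Benjamini–Hochberg step-up *within each group's* trait family, calls at
  q ≤ FDR (default 2%). The per-group family matches reporting call counts
  per population; a sensitivity curve over an FDR grid is available because
  call counts should be stable over roughly 0.5–5%. Null calibration: over
  200 exchangeable 5-population panels the empirical FDR is ≤ 3% at the 2%
  level.
* **Missing data** is pairwise-complete for correlations and variances, and
  complete-case for PCA (traits with any missing value dropped, strains
  standardized per trait), matching ordination practice. PCA components are
  tested by one-way ANOVA (R² = between-SS/total-SS, F-test p) against
  population and source separately.
* **Enrichment** of calls among environment classes uses the two-sided
  Fisher exact test on the (called × in-class) 2×2 table.
* **Atypicality**: Pearson correlation of each strain's profile with the
  group mean profile (computed excluding auxotrophs, which are also excluded
  from every group statistic), ranked ascending; ties break stably by
  strain id.
* **Rate–efficiency structure**: correlations are pooled over all
  (strain, environment) pairs and per environment; the slope of rate against
  √efficiency is computed on the log scale as rate-value vs 0.5 ×
  efficiency-value, since log of a square root halves the log value.

## Clustering

Distance = 1 − Pearson r between strain profiles after per-trait centering,
over pairwise-complete traits (minimum overlap 10 traits, configurable —
panels with strains missing 30% of environments still cluster). Average
linkage (UPGMA) on the complete distance matrix; strains are pre-sorted
lexicographically so equal-distance ties resolve identically regardless of
input order. Dendrograms export to Newick with merge-height differences as
branch lengths. With few strains, per-trait centering shifts random-profile
distances by ≈ +1/(n−1) above 1; this cancels in comparative statements.
Concordance between phenotypic and genetic distance structures is the
Pearson r over the upper-triangle pair vector of shared strains, with an
exclusion list for mosaic genomes whose genetic distances have no clean
evolutionary interpretation.

## Genotype–phenotype association

* **Copy-number ratio**: ln((1+observed)/(1+expected)) reads — the
  pseudo-count keeps zero counts finite and equal counts at exactly 0. The
  log base is a convention; it rescales correlations' slopes, never calls.
  CNV *detection* from raw reads is out of scope: the module consumes
  observed/expected counts or precomputed ratios.
* **Binary alleles** (presence, premature stops): candidate iff the
  Bonferroni-corrected t p < 0.015 *and* the two-sample KS p < 0.15 (both
  configurable; they are per-result conventions, not universal constants).
* **Families**: Bonferroni families are per trait *and per test kind* —
  binary-allele t-tests form one family, CNV correlation tests another,
  since they are different statistics; a per-matrix scope (× trait count) is
  available behind the `family` flag and family sizes are reported per row.
  At study-typical feature counts (hundreds), only large effects (≳4 sd;
  near-complete loss of function) clear these thresholds — by design.
* **QTL cross-check**: a candidate is retained only if its locus (1-based
  in files, converted once to half-open internally) falls inside a
  significant QTL interval of at least one cross. Under a null panel the
  retained count is 0 in ≥ 95% of seeds.

## Linkage mapping

Single-marker regression on parental origin in a haploid F1 panel;
LOD = (n/2)·log₁₀(RSS₀/RSS₁), identical to the two-group Gaussian
likelihood-ratio statistic (asserted against a brute-force oracle to 1e-9).
Missing genotypes are dropped marker-wise (haploid panels are small and
dense; no imputation), markers with < 20 informative offspring or one
parental class score 0 with a flag. The genome-wide threshold is the
(1−α) quantile of max-LOD over seeded trait permutations (α = 0.05 default,
≥ 100 permutations enforced); calibration is verified against independent
null traits. Significant regions are maximal runs of contiguous markers at
or above threshold, expanded by a 25-kb flank (configurable). No interval
mapping, multi-QTL models or epistasis scans.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
multi-population panels (default 5 populations × 5 strains; the
planted-shift benchmark uses 8 per population ≈ a 39-strain panel),
~200 environments × 3 components, n = 2 replicates sharing a strain effect,
within-population variation split into a biological strain effect
(sd 0.3 log₂ units) and per-replicate measurement noise (sd 0.2), random
missingness, and optional planted effects. All effect sizes are in units of
`within_sd` = √(strain_sd² + noise_sd²/n_rep), the SD of a
replicate-averaged trait value, so "a 2-sd shift" refers to the generator's
own noise model. Planted alleles: a stop codon (default 3 carriers in one
population, −3 sd on one trait), a CNV (one population amplified to 2–8
copies, ratio = ln copies + noise, trait slope 2.5 sd per unit ratio —
mirroring near-deterministic dose effects), a presence/absence gene, and
inert decoy features on QTL-free chromosomes. An optional latent factor
couples each environment's rate and efficiency traits to a target
correlation.

Growth curves are a shifted logistic: flat at the inoculum N₀ until the lag,
then logistic toward K = N₀ + efficiency with intrinsic rate
r = (ln 2/Td)/(1 − N₀/K), so the analytic maximal log-slope is exactly
ln 2/Td and the tangent at the growth onset meets the baseline exactly at
the lag. The model is pluggable; effects act directly on the log₂ trait
scale in the fast path used by the statistics benchmarks.

Crosses: per-chromosome two-state Markov recombination (default switch
probability 0.3 between adjacent markers, 130 markers on 16 chromosomes,
96 offspring), one causal marker whose allele effect is scaled to a
requested variance fraction.

What passing synthetic benchmarks does **not** show: real panels have
environment-correlated effects, non-Gaussian trait distributions,
shared-run batch structure and linkage disequilibrium between genotype
features — none of which the generator models. The benchmarks establish
correctness and calibration of the machinery, not field performance.

## Problem sizes in the benchmarks

The acceptance computations use 100 growth curves, 200 null panels of
25 strains × 600 traits, 50 seeds of the 21-strain association scenario
(200 permutations per cross), 100 linkage seeds and 400 calibration trials
with a 1000-permutation threshold — sizes chosen so the whole suite
completes in minutes on one CPU while leaving binomial error well inside
each asserted band.

## Known limitations

* The extractor assumes blank-corrected OD and a single growth phase;
  diauxic shifts produce a single (first-phase-dominated) rate.
* No OD-to-cell-count calibration and no flocculation correction.
* Sequence-level simulation (reads, SNPs) is out of scope; genotype features
  are simulated at the feature-matrix level.
* Dose–response for CNVs is modeled linear in the log ratio; saturating
  responses will attenuate the reported slope.
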