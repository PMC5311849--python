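# Methods

## Model and test

The regional rare-variant burden of individual *i* is summarised as the
proportion of minor alleles carried, and regressed on phenotypes rather
than the other way round ("reverse regression"), which turns joint
multi-phenotype testing into a single weighted linear model:

    z_i = α + β′y_i + ε_i,   ε_i ~ Normal(0, σ²/w_i),   w_i = n_i.

*n*ᵢ counts the region's rare variants with a usable genotype for *i*
(non-missing triplet under expected dosage; a callable genotype under
threshold calling), and *r*ᵢ sums the minor-allele doses over those
variants. The precision weight w_i = n_i realises "each individual's
likelihood contribution is weighted by its number of successfully typed
variants": an individual typed at twice as many variants has residual
variance halved. This is the standard WLS Gaussian likelihood,

    lnL = ½ Σ ln w_i − (N/2)(ln(2π σ̂²) + 1),   σ̂² = (1/N) Σ w_i e_i²,

with σ̂² the maximum-likelihood (divide-by-N) estimator so that lnL and
BIC are mutually coherent; coefficient standard errors instead use the
unbiased residual variance (divide by N − K − 1). Nested models share the
same weights, so the likelihood-ratio statistic 2(lnL_alt − lnL_null) is
asymptotically χ²_K under the null; statistics negative within 1e−8
(numerical noise) are clamped to zero, larger violations raise an
internal-consistency error. A noteworthy consequence of this likelihood
form is that rescaling all weights by a constant leaves lnL differences
and hence p-values unchanged (verified by a test); only relative weights
matter.

Every non-empty subset of the K requested phenotypes is fitted — 2ᴷ − 1
models, full model first, then by decreasing subset size with ties broken
by the phenotype order the user gave. All subsets are fitted on **one
shared complete-case sample** (individuals with n_i > 0 and no missing
value in *any* analysed phenotype): BIC comparisons are only meaningful on
identical data. Each fit is compared against the intercept-only null on
the same individuals and weights. BIC uses k = K + 2 parameters
(intercept, K slopes, residual variance) and the regression sample size;
the intercept/variance convention only shifts all sub-models' BICs by a
shared constant, so ranking is unaffected.

### Residual-variance interpretation

The residual term is treated as a scalar variance with per-individual
precision weights. With one outcome value per individual there is no
covariance matrix to estimate; the weighted scalar form is the standard
WLS likelihood and keeps the nested-model LRT valid.

## Burden construction

Allele-B frequency is computed once per variant from expected dosages
(pAB + 2·pBB, averaged over non-missing included individuals, halved),
regardless of the calling method — frequencies should not depend on the
call threshold. The minor allele is the one with frequency ≤ 0.5 (a tie
at exactly 0.5 designates allele B, a deterministic documented rule).
Variants enter a region's burden iff their position lies inside the
region's 1-based inclusive bounds, their MAF is strictly below the
rare-variant threshold (default 0.05; "< 5%" is strict, so MAF = 0.05
exactly is excluded), they are polymorphic, and they survive any
extract/exclude rs-ID lists. Variants whose genotypes are all missing are
dropped and logged.

Two genotype-use methods are supported: `expected` accumulates expected
minor-allele dosages from the probability triplets; `threshold` hard-calls
the genotype whose probability reaches the cut-off (default 0.9) and
treats everything else as missing. When every triplet is degenerate
(probability 1 on one genotype) the two methods agree exactly.

**Proportion denominator.** The per-variant ratio r_i/n_i can exceed 1
for a diploid (two minor alleles per variant). The default proportion is
computed over allele copies, z_i = r_i/(2n_i) ∈ [0, 1]; a switch
(`--burden_denominator variants`) restores the literal per-variant ratio.
The choice is a pure rescaling of α and β by ½ — log-likelihood
differences, LRT p-values, BIC and model ranking are identical under
either convention.

## File-format conventions

* Sample file: header row, type row (0/D/C/P/B), one individual per row;
  `NA` is the missing token; the `missing` column is metadata only, never
  a filter. Binary (B) columns must contain only 0, 1 or missing.
* GEN file: 5 leading fields + 3N probabilities, streamed line by line so
  memory scales with the variants retained in open regions, not the file.
  Field 1 is treated as the SNP/chromosome code, field 2 as the rs-ID;
  extract/exclude lists match the rs-ID. Triplet sums < 0.1 mean missing
  (the `0 0 0` convention); sums in [0.1, 1.02] are renormalised to 1
  (imputation rounding); larger sums abort the run as corrupt input.
* Region file: `name start end` (or `chrom name start end`), 1-based
  inclusive coordinates matching UCSC-style gene lists; overlapping
  regions are legal and a variant may enter several regions.
* Outputs under a prefix: `.result` (one row per region by default — the
  full model — or one per fitted model with `--print_all`), `.betas`
  (per-phenotype effects and SEs, on request), `.log` (sample counts,
  analysed phenotypes, per-region variant/MAF listings, best-BIC model),
  `.error` (empty iff the run succeeded). Likelihoods and p-values are
  printed in scientific notation with six significant digits; identical
  inputs give byte-identical outputs.

## Numerical choices

The weighted fit solves the √w-scaled design by QR (numpy lstsq); rank
deficiency (collinear phenotypes) marks that model `NA` rather than
aborting the region, and single-phenotype sub-models of a collinear pair
still run. A weighted residual sum below 1e−14 of the outcome's scale is
declared a degenerate variance (constant burden or perfect fit) — the
coefficients are still well defined and are attached to the error for
reporting. Regions need at least K + 3 complete cases (K slopes,
intercept, variance, one residual degree of freedom); otherwise they are
skipped with a logged reason, as are regions with no qualifying variants.

The model enumeration is capped at 16 phenotypes by default (2¹⁶ − 1
models) and can be raised explicitly; the count is always 2ᴷ − 1 (3
models for two phenotypes, 15 for four, 255 for eight).

## Synthetic-study generator

The generator emulates a single-region imputed-cohort study: true
genotypes are binomial(2, MAF) draws per variant, emitted as probability
triplets with mass `certainty` on the truth and the remainder split
evenly (certainty 1 reproduces hard-called data); a `missing_rate`
fraction becomes `0 0 0`. Phenotypes are standardized multivariate normal
with a chosen correlation. Defaults describe the calibration conditions
used throughout the tests: 500 individuals, 20 rare variants with MAFs
evenly spread over 0.5–4%, three phenotypes with the modest pairwise
correlations typical of metabolic traits (0.37, 0.18, 0.19), full
certainty and no missingness.

In **null mode** (all effects zero) phenotypes are independent of
genotypes. In **effect mode** the burden is regenerated from the
phenotypes so that z_i = α + Σβ_k y_ik + ε_i holds with ε precision-
weighted by n_i — the model's own generative direction, which is the
correct parameter-recovery design for a reverse regression. The target
proportion is projected back to integer allele counts (nearest count,
clipped to [0, 2n_i], minor alleles placed uniformly over the
individual's typed allele slots), an approximation with granularity
1/(2n_i) whose rounding error behaves as additional centred noise. The
generator refuses effect configurations pushing more than 1% of target
proportions outside [0, 1], since clipping would otherwise truncate the
residual distribution and bias recovery; the recovery harness therefore
uses an intercept of 0.10 with slopes ≈ ±0.02 and residual SD 0.04.

What the generator does **not** emulate: linkage disequilibrium between
variants, haplotype structure, population stratification, genotyping
batch effects, or non-Gaussian phenotypes. Passing calibration and
recovery tests therefore demonstrates the estimator's correctness under
its assumed sampling model, not robustness to confounding in real
cohorts.

## Test and calibration problem sizes

Null calibration uses 5,000 single-region replicates at N = 500, 20 rare
variants, K = 3, checking the full-model rejection rate at α = 0.05
against [0.04, 0.06] and the LRT statistic against χ²₃ by a
Kolmogorov–Smirnov test. Parameter recovery uses 1,000 effect-mode
replicates and requires mean estimates within 3 Monte-Carlo standard
errors of truth. The weighted solver is checked against a loop-coded
normal-equations oracle (200 random instances, N ≤ 50, K ≤ 3, 1e−8
relative) and against an established WLS implementation on a fixed
instance.

## Known limitations

Binary outcomes are accepted as predictors but the burden model is
linear-Gaussian; covariates must be adjusted out of the phenotypes
upstream (e.g. analysing residuals, as is common practice); p-values are
not corrected for multiple testing (`bonferroni_threshold` is a
documentation helper); no functional weighting of variants or
variance-component (kernel) statistics; BGEN/VCF input and on-the-fly
imputation are out of scope — imputation-quality filtering is expected
upstream via exclusion lists. Absolute log-likelihood and BIC values
depend on the weighted-likelihood normalisation; only differences across
sub-models of the same region are meaningful.
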