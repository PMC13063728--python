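# Methods

This note documents the statistical model behind `histoqtl`, the numerical
choices made where the design was open, what the synthetic-data generator
does and does not emulate, and known limitations.

## The variance-component score test

The association model treats the genotype as the outcome:

g = F α + u, u ~ N(0, σx² K(X)), with K(X) = X̃ X̃ᵀ the cosine-similarity
kernel of the row-normalized embeddings. Testing σx² > 0 by a score test
gives Q = rᵀ K r = ‖X̃ᵀ r‖², with r = M g the covariate residual and
M = I − F(FᵀF)⁻¹Fᵀ. Under the null and Gaussian residual noise,
Q ~ Σᵢ σ² μᵢ χ²₁ with μᵢ the eigenvalues of X̃ᵀ M X̃ — an L × L problem, so a
scan costs O(NL) per variant after an O(NL² + L³) per-trait setup. The test
equals the kernel quadratic form a dense N × N computation would give to
1e-8 relative (asserted over random instances in the suite).

Why genotype-as-outcome: it makes the multivariate embedding enter only
through the kernel, sidesteps an L-dimensional multivariate regression, and
(with the Gaussian genotype likelihood) turns the null model into a single
OLS fit per variant. Individuals are treated as unrelated; population
structure is absorbed by genetic-PC covariates rather than a kinship random
effect.

### Null distribution: exact ratio form

The p-value reported by default is the exact finite-sample tail of the
standardized statistic. Because σ̂² = rᵀr/(N−K) is computed from the same
residual as Q, the event {Q/σ̂² > t} is {rᵀ(K − t/(N−K) I) r > 0}: a signed
chi-square mixture with weights {μᵢ − t/(N−K)} plus −t/(N−K) with
multiplicity N−K−L. Its probability is evaluated by numerical inversion of
the characteristic function. This removes the O(1/√N) distortion of
plugging σ̂² into the asymptotic mixture — the same χ² vs F phenomenon
familiar from single-coefficient tests — which is measurable at N of a few
hundred: at N = 200 the plug-in p-value differs from a 100,000-permutation
empirical p by ~7 × 10⁻³ in the mid-range, outside the permutation 99% CI,
while the exact ratio form agrees within it (asserted in the suite).

### Mixture tails: characteristic-function inversion

`davies_pvalue` evaluates P(Σ λᵢ χ²₁ > Q) through Imhof's integral
representation,

S(Q) = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,

with θ(u) = ½Σ atan(λᵢ u) − Qu/2 and ρ(u) = Π(1 + λᵢ²u²)^¼. The integral is
computed by panel-wise 12-point Gauss–Legendre quadrature with panel widths
capped at half the local oscillation period and at geometric growth (so the
power-law amplitude decay is resolved), truncated at a point U beyond which
an exact two-term integration-by-parts correction h(U)cosθ(U) −
h₂(U)sinθ(U) (h = g/θ′, h₂ = h′/θ′) accounts for the remaining tail with a
bounded third-order error. Accuracy target is 1e-9 absolute; spot checks
against 40-digit quadrature show ~1e-11 agreement, and a two-resolution
error estimate drives the `converged` flag. Single or equal weights use the
exact chi-square instead. Eigen-weights below 1e-12 of the largest are
dropped. p-values below 1e-12 are beyond absolute inversion accuracy and
flagged for fallback.

The signed-mixture integral of the ratio form uses the same panel scheme;
there the amplitude decays like u^(−1−(N−K)/2), so integration simply stops
where the amplitude underflows.

### Liu fallback

When inversion does not converge, or the p-value underflows, the
moment-matched noncentral chi-square approximation is used, with the
kurtosis-based modification of the degrees of freedom in the
skewness-deficient branch (the convention of modern kernel association
software). The modification matters: at p ≈ 2 × 10⁻⁵ the modified form is
within ~15% of the exact tail where the original is off by ~2×. The method
used per variant ("davies"/"liu") is recorded in the scan output.

σ̂² uses the unbiased denominator N−K. Any joint rescaling of (Q, λ) leaves
p unchanged, so the statistic's normalization convention is immaterial;
this invariance is asserted in the suite.

## Scanning and multi-trait FWER control

A scan tests every (trait, variant) pair. Within a trait all variants share
the base spectrum μ, so p = S(Q/σ̂²) for one decreasing function S; two
consequences are exploited:

* the per-scan minimum p-value needs a single tail evaluation at
  max(Q/σ̂²) — permutation replicates cost one CF inversion each;
* a documented `fast` scan mode evaluates S exactly at 96 grid points,
  interpolates log p monotonically (PCHIP) in between, and re-evaluates the
  most significant variants exactly. Default scans are exact per variant.

The FWER procedure permutes genotype rows (individuals) jointly across all
variants — preserving LD and the covariate/embedding structure — reruns the
scan, and records min-P per permutation. Permutations are drawn
independently per trait from seeded substreams. The pooled min-P
distribution across traits × permutations yields the empirical α-quantile
(linear-interpolation convention), divided by the number of traits for the
final threshold (α = 0.2 by default, matching a 20% family-wise level). On
a fully null synthetic genome the resulting family-wise rejection rate is
within binomial noise of α (asserted at 8 traits × 2,000 variants × 50
permutations × 200 replicates).

## Colocalization

Per-variant evidence is the Schwarz (BIC) log Bayes factor with one extra
parameter: lbf = (Λ − ln N)/2, Λ the 1-df chi-square implied by the score
test p-value. The 1-df convention is kept even though the score statistic's
null is a mixture; the resulting BF is an asymptotic approximation, not a
calibrated posterior quantity, and is validated behaviorally (shared-causal
simulations give median PP-H4 > 0.8; distinct-causal give PP-H3 ≫ PP-H4).
Posterior algebra is the standard single-causal-variant scheme over H0–H4
with priors p1 = p2 = 1e-4, p12 = 1e-5, computed in log space with
log-sum-exp; H3 uses the exact pairwise-exclusion sum. Natural logs
throughout. External traits supplied as (beta, se) are converted with the
asymptotic BF under a N(0, 0.2²) effect prior — an interface convenience,
with the prior SD exposed. Note that adding a constant to one trait's lbf
rescales H1/H3/H4 jointly relative to H0/H2; only ratios within those
blocks are translation invariant. Genomic windows are inclusive on both
ends, 1 Mb by default. p-values below 1e-300 are clipped (with a warning)
before quantile inversion.

## Effect axis

The direction of a variant's effect in embedding space is the covariate-
residualized cross-covariance X_resᵀ g_res, unit-normalized and oriented so
higher alt dosage raises projection scores — the per-dimension OLS effect
vector, which is the natural point estimate under the model. A BLUP-style
shrunken estimate differs only by per-dimension scaling under correlated
embeddings; the package estimates the direction, and the suite tests
recovery of planted directions (mean |cos| > 0.9 at n = 2,000, v = 1%),
not equality to any particular scaling. Extreme representative embeddings
average patches inside closed percentile bands (1st–5th, 95th–99th by
default) under the linear-interpolation percentile convention, ties broken
by stable patch order; interpolation between them is linear; slides are
flagged as extreme when ≥ 40 of their patches fall in the global top or
bottom 5% of scores.

## Expression prediction

For encoder benchmarking, expression is the outcome of y = Fα + u + e with
u ~ N(0, σx² K) on the training kernel. The single hyperparameter
δ = σe²/σx² is selected by profile maximum marginal likelihood on a
41-point log grid over [1e-4, 1e4] (α and σx² profiled out analytically via
one eigendecomposition of K). Because K has unit diagonal, the implied
signal fraction is 1/(1+δ); it recovers a simulated 50% fraction within
[0.35, 0.65] at n = 500. Out-of-sample prediction is the BLUP
ŷ* = F*α̂ + K*,t(K + δI)⁻¹(y − Fα̂), identical to the conditional Gaussian
mean and to kernel ridge regression on residualized data; a leverage-based
leave-one-out predictor is provided for within-train validation. Evaluation
is Spearman correlation on held-out samples.

Reconstruction deterioration uses Steiger's (1980) z for two dependent
correlations sharing the observed-expression variable, with the pooled-
correlation covariance term and Fisher-z transformation; the alternative is
one-sided (reconstruction weaker than original). Screening across genes is
Bonferroni at 0.05.

## Cluster signatures

Clustering itself (PCA, neighbor graph, Leiden) is consumed as precomputed
labels. A cluster is retained for genetic analysis when at least 10 of its
patches appear in each of at least 650 slides (both thresholds exposed).
Slide-level abundance is the proportion of the slide's patches in the
cluster; abundance–expression association is a univariate Gaussian LM on
rank-inverse-normal-transformed expression, assessed by the likelihood
ratio Λ = n·ln(RSS₀/RSS₁) against χ²₁ — a monotone transform of the exact
F statistic, asserted per instance in the suite.

## Synthetic cohorts, calibration and power

`simulate_cohort` draws g ~ Binomial(2, maf), covariates (intercept, sex ~
Bernoulli(½), standardized age, four standard-normal genetic PCs), and
builds X = F_c A + (g − ḡ)·s bᵀ + E with isotropic unit-variance noise. The
effect direction b is a single random unit vector per seed; s is chosen so
the genetic component contributes exactly the fraction v of the total trace
variance, using population variances given the allele frequency (2·maf·(1−maf))
so small cohorts remain honest about sampling noise. Covariates jointly
explain 20% of trace variance by default (exposed in `SimConfig`); the
causal allele frequency defaults to 0.25, a mid-range common variant.
Monomorphic genotype draws are resampled with a logged count. A coupled
generator produces two embedding sets sharing (or not) a causal variant
from a common panel for colocalization checks.

What the generator emulates: the additive covariate + single-variant +
Gaussian-noise structure of embeddings, at the cohort sizes (650–10,000)
and variance fractions (0.01%–1%) of the reference power design. What it
does not: LD between variants (the panel is independent; LD enters the
pipeline only through the row-permutation design of the FWER procedure),
non-Gaussian embedding noise, patch-level heteroscedasticity, batch/site
effects, or multi-directional genetic effects (a config extension). Passing
calibration and power checks on these cohorts therefore validates the
statistical machinery, not robustness to those real-data complications.

Calibration runs test independent null variants against one simulated
embedding set; at n = 650, L = 64, 2,000 tests the suite requires KS
uniformity (p > 0.01), empirical level at α = 0.05 within 3 binomial SEs
and genomic inflation within [0.9, 1.1]. Power runs use 50 seeds per
(n, v) cell on a 3 × 3 subgrid of the reference design at α = 5 × 10⁻⁸,
asserting monotonicity in n and v (within 2 SE), power ≥ 0.95 at
n = 10,000 / v = 1%, and no rejections at v = 0. These problem sizes are
the package's test design; the full 5 × 7 × 100-seed grid is available
through `power_run` / `histoqtl simulate-power`.

## Degenerate inputs and numerical conventions

Variant positions are 1-based; windows are inclusive. Missing genotypes are
mean-imputed per variant before testing; all-missing variants are an error
naming the variant. Multi-allelic VCF records are skipped with a warning
(a flag splits them instead). Matrices are inner-joined on sample id with
logged drop counts. Zero-norm embedding rows are an error naming the sample
(cosine similarity undefined). Genotypes numerically inside the covariate
span are flagged untested rather than dropped. The rank-inverse-normal
transform uses the Blom offset (3/8) with average ranks for ties and
rejects constant input. Quantiles everywhere use linear interpolation
between order statistics.

## Known limitations

* The Gaussian genotype likelihood is the only one implemented (the
  binomial variant is a documented non-goal); dosages are treated as
  continuous outcomes.
* Relatedness is not modeled beyond PC adjustment.
* Colocalization assumes a single causal variant per trait per window and
  takes the 1-df BIC shortcut for a mixture-null statistic.
* The effect-axis estimator identifies a direction, not an effect size with
  uncertainty.
* p-values below ~1e-12 rely on the moment-matched approximation and are
  order-of-magnitude quantities, comfortably beyond any threshold used here.
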