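# Methods

This note records the statistical models implemented in `mixewas`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Data scales

Methylation arrives as beta values, fractions in [0, 1] computed from
fluorescence as `max(M,0) / (max(M,0) + max(U,0) + 100)`; the 100-unit
offset regularises low-intensity probes. Deconvolution operates on the
beta scale, where the factorisation has a methylome interpretation and
the [0, 1] box constraint is meaningful. Association models operate on M
values, `log2(β/(1−β))`, whose variance is approximately level-free;
betas are clipped to `[ε, 1−ε]` with `ε = 1e-6` before the logit, which
keeps M finite without materially moving interior values. Probes carrying
any exclusion flag (sex chromosome, cross-reactive, SNP overlap) and any
probe with missing betas are removed before modelling; imputation is out
of scope.

## Cell-mixture deconvolution

Model: `Y ≈ Mu Ωᵀ` with `Y` the m×n beta matrix, `Mu ∈ [0,1]^{m×K}` the
latent cell-type methylomes and each row of `Ω ∈ R^{n×K}` on the
probability simplex. Both sub-problems are convex; the fit alternates

1. simplex-constrained least squares for all rows of Ω, and
2. box-constrained least squares for all rows of Mu,

each solved by projected gradient descent with the exact Lipschitz step
`1/(2·λmax)` of its quadratic, so every step — and hence the recorded
objective trace — is monotone non-increasing. Iteration stops when the
relative objective decrease falls below `tol` (default 1e-6) or after
`max_iter` outer iterations (default 300; a fit returned with
`converged=False` is still the best iterate found, and near-flat
over-parameterised fits commonly end this way without practical
consequence). `Mu` is initialised from k-means++ centroids of the
samples (seeded), and samples are internally processed in sorted-id
order so results are invariant to input column order. Components are
canonically ordered by descending mean proportion, which also makes the
"smallest component" dropped from adjusted designs well defined.

**Identifiability.** A convex factorisation is unique only when some
specimens lie near the simplex vertices (near-pure cell populations).
When compositions are tightly concentrated, any simplex containing the
data hull fits equally well and absolute proportions are recoverable
only up to that geometry; the converged fit then underestimates spread
(observed mean absolute error ≈ 0.08 at Dirichlet concentration 30
regardless of iteration count). Proportion-recovery benchmarks therefore
draw compositions from a flat Dirichlet (balanced means, concentration =
K), the standard identifiability regime, while cohort-level simulations
keep the concentrated default that mimics real tissue. Adjustment in the
EWAS depends only on the span of the estimated proportions, not on
vertex identification, which is why confounding control works even in
the concentrated regime.

**Choosing K.** Specimens are resampled with replacement (`n_boot`,
default 100; tests use 15–50) after restriction to the 10,000 most
variable probes. For each resample and each candidate K the model is
refitted and scored on the out-of-bag specimens by bi-cross-validation:
each held-out specimen's proportions are estimated by simplex projection
using a random half of the probes, and the deviance is the mean squared
residual on the other half. Scoring on probes not used for the
projection is essential — a plain projection residual decreases
monotonically in K even on unstructured noise, whereas the probe-split
score recovers the true order on structured data and prefers K = 1 on
noise. `chosen_K` is the smallest K attaining the minimal mean deviance.
On concentrated-composition cohorts the deviance flattens at the true
order and the argmin may land one component past the elbow; the paired
summary table is emitted so users can see the flatness, mirroring the
cohort-to-cohort K instability familiar from real data.

## Mixture–covariate association

For each candidate K and each component, the estimated proportion vector
is regressed on the covariate with a logit-link quasi-binomial model:
variance `φ·μ(1−μ)`, dispersion `φ` from Pearson residuals (floored at
1e-10 so perfectly separated proportions stay testable), Wald t on
n − 2 degrees of freedom. Constant proportions or covariates give p = 1
by convention. The observed statistic is the minimum p over all
components and all K; its reference distribution permutes the covariate
against the *fixed* estimated proportions B times (add-one p-value,
bounded below by 1/(B+1)). The deconvolution never sees the covariate,
so its output is invariant under permutation and re-running it per
permutation would only add noise; this is the computationally honest
reading of spanning the null over the same K grid. The IRLS is
hand-vectorised across permutation columns (closed-form two-parameter
weighted least squares), and its agreement with the statsmodels
quasi-binomial GLM is asserted in the test suite.

## Moderated EWAS

Per CpG, ordinary least squares of M values on a shared design:
intercept, the risk factors (categoricals expanded against the most
frequent level), and — in adjusted models — all estimated proportion
columns except the smallest-mean component (the rows of Ω sum to one, so
including all K would be collinear). Samples missing a requested
covariate are dropped with a logged count. Residual variances are
shrunk by the empirical-Bayes scheme of moderated t-statistics: the
prior `(d0, s0²)` is estimated by moment matching on log residual
variances (digamma/trigamma inversion by Newton iteration), the
posterior variance is `(d0·s0² + d·s²)/(d0 + d)`, and the moderated t
has `d0 + d` degrees of freedom. Setting d0 = 0 recovers the ordinary
t exactly (asserted to 1e-10); d0 = ∞ pools all probes to `s0²`.
Benjamini–Hochberg q-values are computed per covariate across probes;
the genome-wide threshold defaults to Q = 0.01. The delta coefficient,
`coef(unadjusted) − coef(adjusted)`, flags loci whose apparent effect is
carried by composition. Hyper/hypomethylation labels follow the sign of
the age coefficient.

**A known limitation of reference-free adjustment.** When true
covariate effects are a non-trivial share of total variance (as in a
small simulated array where 5% of probes carry strong planted effects),
the effect direction leaks into the estimated components; adjusting for
them then both attenuates true effects and induces small compensating
age coefficients at null probes where cell types diverge, inflating the
adjusted model's FDR above nominal (observed 0.05–0.14 by seed at
sensitivity 1.0). On a real-scale array the planted share is orders of
magnitude smaller. The power benchmark therefore plants effects without
composition drift and evaluates the design-matched (unadjusted) model,
while confounding control is benchmarked separately on drift-only nulls.

## Enrichment and progression

Enrichment is a 2×2 Fisher exact test per region set: significant CpGs
(split by coefficient sign into hyper/hypo strata) versus the rest of
the analysis universe, counted inside/outside the set's merged
intervals. A probe at annotated position p is inside `(start, end)` iff
`start ≤ p < end`. The odds ratio is the sample OR `ad/bc`; the 95% CI
uses the log-OR normal approximation with a 0.5 continuity correction
only when a zero cell exists; BH q-values are assigned across sets
within each direction, and empty strata are emitted as "skipped" rather
than dropped. The matched background sampler draws, per stratum of the
matching field (default CpG-island relation), exactly as many non-query
probes as the query holds — usable only because island relation tracks
methylation level, which equalises the M-value variance of matched
coefficients. Progression analysis fits age-adjusted moderated models of
tumour-vs-normal status over the shared probes and compares the
coefficient distribution at the query CpGs against the matched
background with a two-sample Kolmogorov–Smirnov test (exact p when
n·m ≤ 10,000, asymptotic otherwise). CpG–expression correlation is
Spearman's rank over shared samples (≥ 5 required), retaining gene
region for context summaries.

## Epigenetic clocks

A clock is data: a probe→weight table, an intercept, and a calibration
transform (`identity`, or the log-linear form with an adult-age
breakpoint: `T(a) = log((a+1)/(A+1))` below A, `(a−A)/(A+1)` above,
inverted after prediction). Mean-beta ("mitotic score") clocks average
the betas over the CpG set. Prediction requires ≥ 95% of the clock's
CpGs (configurable); NaN betas at present probes error out or are
imputed with the probe's cohort mean. Age acceleration is the OLS
residual of predicted age on chronological age (orthogonal to
chronological age by construction, residuals summing to zero), and its
risk-factor associations are reported both per covariate and jointly,
with constant terms dropped.

## The synthetic generator

What it emulates: K latent methylomes with a shared bimodal baseline
(Beta(0.4, 0.4)) and per-cell-type divergence at a configurable fraction
of probes (default 30% divergent); Dirichlet compositions (concentration
30) whose mean shifts linearly with age along a fixed direction
(`drift`/year on the leading component, mirrored on the smallest);
planted age-associated CpGs as logit-scale slopes (default 0.02
M-units/year, 69% positive, matching the hypermethylation predominance
of age drift), placed at intermediate-methylation probes where age drift
occurs in vivo and a logit shift is observable; truncated-Gaussian
beta-scale noise (sd 0.03); island relation assigned from baseline
methylation (islands unmethylated → open sea methylated), uniform gene
regions, autosomal positions; region sets covering planted CpGs at an
elevated rate against a uniform background; tumour cohorts from the same
generative model whose planted CpGs carry an extra
`(exaggeration−1)·slope·20 years` of drift; and invertible synthetic
clocks whose linear predictor equals the transformed target age.

What it does not emulate: Infinium probe-type chemistry, array batch
structure, the Beta-distributed error of real normalized betas,
correlated probe blocks, or genuine biological annotation; passing tests
demonstrate the statistical machinery under the stated generative
assumptions, not performance on real arrays.

## Problem sizes used by the test suite and acceptance script

Recovery fixtures use n = 100 × m = 2000 (proportions), 20 datasets of
n = 50 × m = 300 with 50 bootstraps (K selection), ten seeds of
n = 100 × m = 2000 (confounding and power), 100 null runs of
n = 50 × m = 400 at B = 199 (permutation calibration), twenty seeds of
n = 80 × m = 1000 (enrichment), and fifty seeds of n = 60 × m = 800
with 40 tumours (progression). The acceptance script runs the same
designs at somewhat smaller replicate counts, derives every stream from
its `--seed`, and completes in a few minutes on one CPU.
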