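# mixewas

Reference-free, cell-mixture-adjusted epigenome-wide association analysis
for DNA methylation array data.

Bulk tissue is a mixture of cell types with distinct methylomes, so
differences in cellular composition across subjects confound per-CpG
association tests: a risk factor that shifts composition (age is the
canonical example) produces thousands of spurious CpG hits if composition
is ignored. `mixewas` implements the reference-free workflow for this
problem, aimed at epigenetic epidemiologists analysing normalized
beta-value matrices (450K/EPIC-style) with subject risk-factor data:

- **Cell-mixture deconvolution** — factorise the CpG-by-sample beta matrix
  as `Y ≈ Mu Ωᵀ`, a convex variant of non-negative matrix factorisation
  with `Mu ∈ [0,1]^{m×K}` (putative cell-type methylomes) and each row of
  `Ω` on the probability simplex (mixture proportions). The number of
  putative cell types K is selected by bootstrap: resample specimens with
  replacement, refit, and score each K by out-of-bag reconstruction
  deviance.
- **Mixture–covariate association** — per-component quasi-binomial
  regressions of proportions on a covariate, combined across components
  and across all candidate K by a min-P permutation test.
- **Moderated EWAS with confounding diagnostics** — per-CpG linear models
  of M values (`M = log2(β/(1−β))`) on risk factors, with and without the
  estimated proportions as covariates (all components but the
  smallest-mean one, to avoid collinearity), empirical-Bayes variance
  shrinkage (`s̃² = (d₀s₀² + d s²)/(d₀+d)`), Benjamini–Hochberg Q values,
  and the per-CpG *delta coefficient* (unadjusted − adjusted effect) that
  flags composition-confounded loci.
- **Direction-stratified region enrichment** — Fisher exact 2×2 tests of
  significant CpGs (split into hyper- and hypomethylated strata) against
  labelled genomic interval sets, over the analysis universe as
  background; plus annotation-matched background resampling and
  two-sample Kolmogorov–Smirnov contrasts for tumour-progression
  analyses.
- **Epigenetic clocks** — coefficient-table DNA-methylation age predictors
  (linear with optional log-linear calibration, or mean-beta mitotic
  scores), age acceleration as the residual of DNAm age on chronological
  age, and acceleration–risk-factor regressions.
- **Synthetic cohorts with ground truth** — a first-class generator for
  mixtures whose composition drifts with age, planted age-associated CpGs
  (majority hypermethylating), region sets with planted enrichment, and
  paired tumour cohorts with exaggerated deviations, so every stage is
  testable end to end without any data download.

## Worked example

Two synthetic cohorts of n = 100 subjects × 2000 CpGs separate the two
phenomena the pipeline must handle. In cohort A, cell composition drifts
with age (0.004/year on the leading component) but **no** CpG has a true
age effect; in cohort B, 100 CpGs carry true age effects (slope 0.02
M-units/year, 69% hypermethylating) and composition is stable.

```python
from mixewas import (simulate_cohort, select_k, ReferenceFreeMixture,
                     to_mvalues, build_design, CpGAssociationModel,
                     delta_coefficients, test_metadata_association)

bm, sheet, ann, truth = simulate_cohort(n=100, m=2000, K=3, drift=0.004, seed=7)
ksel = select_k(bm, k_grid=[1, 2, 3, 4], n_boot=30, seed=1)
print(ksel.summary())
```

```
Bootstrap K selection (30 resamples, seed 1)
  K=1: deviance 0.00207309
  K=2: deviance 0.0012412
  K=3: deviance 0.000879499
  K=4: deviance 0.00087212 <- chosen
```

The deviance drops sharply up to the generating order (K = 3) and then
flattens; with tightly concentrated compositions the bootstrap argmin can
land one past the elbow, exactly the kind of between-cohort K instability
seen with real tissue, and the downstream adjustment is insensitive to
the extra component. The permutation test ties composition to age:

```python
mixture = ReferenceFreeMixture(bm).fit(ksel.chosen_K, seed=2)
assoc = test_metadata_association(bm, sheet, "age", k_grid=[1, 2, 3, 4],
                                  B=999, seed=3)
print(assoc.summary())
```

```
Mixture-association permutation test for 'age'
  K grid: [1, 2, 3, 4], permutations: 999
  observed min p = 2.18e-15
  permutation p = 0.001
```

Composition confounding in cohort A, and its removal by adjustment:

```python
mv = to_mvalues(bm)
adjusted = CpGAssociationModel(mv, build_design(sheet, ["age"], mixture=mixture)).fit("age")
unadjusted = CpGAssociationModel(mv, build_design(sheet, ["age"])).fit("age")
print(unadjusted.summary()); print(adjusted.summary())
```

```
EWAS of age (unadjusted model, n = 100 samples, 2000 probes)
  prior df d0 = 0.808, prior variance s0^2 = 0.129
  significant at Q < 0.01: 408 (217 hypermethylated, 191 hypomethylated)
EWAS of age (adjusted model, n = 100 samples, 2000 probes)
  prior df d0 = 0.742, prior variance s0^2 = 0.0782
  significant at Q < 0.01: 0 (0 hypermethylated, 0 hypomethylated)
```

All 408 unadjusted hits are composition artefacts — no CpG in cohort A
has a true age effect — and the adjusted model reports none. In cohort B
the same machinery recovers every planted locus with the planted
direction split:

```python
bm2, sheet2, ann2, truth2 = simulate_cohort(n=100, m=2000, K=3, drift=0.0,
                                            n_age_cpgs=100, slope=0.02, seed=8)
res2 = CpGAssociationModel(to_mvalues(bm2), build_design(sheet2, ["age"])).fit("age")
print(res2.summary())
sig = res2.significant(0.01).index
print(f"planted CpGs recovered: {sig.isin(truth2.age_cpg_ids).sum()} of 100")
```

```
EWAS of age (unadjusted model, n = 100 samples, 2000 probes)
  prior df d0 = 0.819, prior variance s0^2 = 0.121
  significant at Q < 0.01: 100 (69 hypermethylated, 31 hypomethylated)
planted CpGs recovered: 100 of 100
```

## Command line

A thin CLI mirrors the library: `mixewas simulate` writes a fixture
bundle with its truth JSON; `deconvolve`, `ewas`, `mixture-assoc`,
`enrich`, `progression` and `clock` run single stages on files;
`mixewas run --config config.yaml` executes the full discovery pipeline
(filter → K selection → deconvolution → permutation tests → adjusted and
unadjusted EWAS with deltas → stratified enrichment) with a run manifest,
and `mixewas simulate-and-run` is an all-synthetic end-to-end demo. Exit
codes: 0 success, 1 validation error, 2 stage failure.

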