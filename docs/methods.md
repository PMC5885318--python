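# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `phewas_power`.

## Genotype model

Genotypes are simulated per individual as i.i.d. multinomial draws from the
Hardy–Weinberg probabilities ((1−q)², 2q(1−q), q²) at minor allele frequency
q ∈ [0, 0.5].  Drawing individuals (rather than allele pairs) is equivalent
under HWE and simpler to test.  q = 0 is accepted as a degenerate
monomorphic SNP for edge-case testing; q > 0.5 is rejected (the minor allele
is by definition the rarer one).  SNPs are mutually independent: no linkage
disequilibrium, no population structure, no relatedness.  Noise SNPs use the
same sampler at the same MAF and are never connected to any phenotype.

## Binary-trait model

A simulation cell's effect size is a penetrance function over minor-allele
counts, built from two probabilities:

* **baseline f₀** — disease prevalence among non-carriers, default 0.1.
  This is interpreted on the risk scale (a prevalence), not as a logistic
  intercept; the two readings differ (logit⁻¹(0.1) ≈ 0.52 would be an
  implausible prevalence) and the prevalence reading keeps the null model
  exactly exchangeable.
* **penetrance f₂** — disease risk of minor-allele homozygotes.

The heterozygote risk is the midpoint f₁ = (f₀+f₂)/2, i.e. additive on the
risk scale, matching the additive test model.  Risk is always attached to
the minor allele; protective effects are out of scope.

Cohorts are sampled retrospectively (case-control): individuals are
generated genotype-first from HWE, status ~ Bernoulli(f(g)), and accepted
into the case or control stratum until both quotas fill (n_cases cases,
round(ratio × n_cases) controls; "1:2" means ratio = 2).  Draws are capped
at 10⁷ per cohort so a degenerate penetrance (no achievable cases or
controls) raises instead of looping forever.  Under this scheme the case
genotype distribution is HWE(g)·f(g) normalised, and the control
distribution HWE(g)·(1−f(g)) normalised — both available in closed form as
test oracles.

## Quantitative-trait model

The same penetrance function drives a liability-threshold-calibrated
mean-shift model: Y = βg + ε with ε ~ N(0,1) and

β = (Φ⁻¹(1−f₀) − Φ⁻¹(1−f₂)) / 2,

so that P(Y > Φ⁻¹(1−f₀) | g=0) = f₀ and P(Y > Φ⁻¹(1−f₀) | g=2) = f₂.
Carriers are thereby enriched in the upper tail of the trait distribution
(and depleted from the lower tail), the trait remains approximately
normalized at low MAF, and power admits the closed-form oracle below.  This
is one faithful mapping of a penetrance scalar onto a continuous trait;
alternatives (e.g. dichotomising an explicit latent liability) would give
the same additive structure with a rescaled β.

## Association tests

Binary: maximum-likelihood logistic regression of status on g, fit by
Newton/IRLS on the aggregated 2×3 genotype-by-status table (the sufficient
statistic), tolerance 1e-8 on the log-likelihood change, at most 50
iterations with step halving.  Aggregation makes each fit O(iterations × 3)
regardless of cohort size, which is what keeps a 40-test × 1000-replicate
cell around a second of CPU.

The reported p-value is the **likelihood-ratio test** of slope = 0 (the
statistic is the signed likelihood root, so it reads like a z-score).  The
Wald z = b̂/se was evaluated and rejected for this purpose: at
PheWAS-typical strata (50–200 cases, MAF ≈ 0.05) and tail thresholds like
α = 2.5×10⁻⁴, the Wald statistic's far tail is deflated several-fold — the
standard error grows with |b̂| (the Hauck–Donner effect), so extreme
z-values are systematically under-produced and the empirical Type I error
falls well below nominal.  In measured 1000-replicate batteries the LRT
rejection counts sit inside the exact-binomial 99% band of the nominal α
while Wald counts fall below it; the score (Cochran–Armitage trend) test
was also deflated in the smallest cells.  β̂ and the Wald SE are still
reported for effect interpretation, and the three statistics agree
asymptotically (a unit test checks squared-likelihood-root vs trend
chi-square agreement on large null data).

Degenerate inputs — constant genotype, single-class status, complete
separation (detected as non-convergence or |b̂| > 30) — return a
non-converged result with NaN p-value rather than raising.  The power
engine counts these as non-significant and tallies them per cell
(`n_nonconverged`); this is conservative in extreme cells (e.g. 10 cases at
MAF 0.01, where the minor-allele strata are usually empty).

Quantitative: ordinary least squares with intercept; exact two-sided t-test
on the slope with n−2 df.  A numerically constant trait yields slope 0 /
p = 1; an exactly collinear trait yields p = 0.

## Power engine

Each replicate dataset is 4 SNPs × 10 phenotypes (binary) or 4 × 1
(quantitative) with one signal pair; 3 noise SNPs at the signal MAF; 9 noise
phenotypes as uniformly random label permutations with identical
case/control counts.  Power counts the signal pair only; Type I error
counts the 39 (or 3) noise pairs — matching the separate power and Type-I
surfaces the method is meant to reproduce.  Binomial Monte-Carlo standard
errors accompany both.

Per-test thresholds: binary α = 0.00025 (Bonferroni 0.01/40); quantitative
α = 0.004, kept as a named constant — the conventional operating threshold
for the 4-test battery — rather than the strict split 0.01/4 = 0.0025.
Results are insensitive to that difference; an explicit `family_level` or
`alpha` overrides either.

Seeding: each replicate's generator is `SeedSequence(master_seed,
spawn_key=(cell_index, replicate_index))`, so grid results are
bit-identical for any worker count and any execution order.  `run_grid`
parallelises over cells with joblib when `workers > 1`.

Closed-form oracles: quantitative power is
Φ(−z₁₋α/₂ + δ) + Φ(−z₁₋α/₂ − δ) with δ = β·√(n·2q(1−q)); binary power uses
the two-proportion contrast of case vs control minor-allele frequencies
implied by the retrospective sampling distributions.  Both are
approximations (known σ, expected allele counts) used as cross-checks, not
as the estimator.

Default grids: cases {10, 20, 50, 100, 200, 500, 1000}; ratios {1, 2, 4};
MAF {0.01, 0.05, 0.10, 0.25}; penetrance {0.10 … 0.30}; quantitative n
{10 … 25000}.  Replicates default to 1000 per cell.  The test suite runs
reduced configurations (200–1000 replicates, 3–12 cells per property) so
the whole suite completes in a few minutes of CPU; the estimates at those
sizes carry MC standard errors of a few percent, which the assertions
account for explicitly.

## What the simulations do and do not emulate

The generator reproduces the *sampling* structure of a PheWAS — varying
case counts, unbalanced unmatched case:control ratios, Bonferroni-scale
thresholds, independent noise dimensions — under idealised genetics: HWE,
no LD, no covariates or confounding, no ascertainment bias, additive
effects only, one causal SNP per phenotype.  Passing tests therefore
validate the power arithmetic under these assumptions; they do not show
that a real EHR phenotype with the same nominal case count has that power —
misclassification, relatedness, stratification and covariate adjustment all
move real-data power, typically downward.

One consequence of the retrospective sampler worth noting: in
mid-transition cells (power far from both 0 and 1, e.g. 200 cases, MAF
0.25, penetrance 0.25) increasing the control:case ratio does raise power
noticeably, because extra controls shrink the allele-frequency-contrast
standard error.  The "ratio has negligible effect" behaviour holds on
near-saturated or near-null surfaces, which is where the headline
case-count recommendations live; the trend test in the acceptance suite
checks exactly those cells.

## EHR phenotype selection

`define_cases` implements the rule-of-three: a patient is a case for an
ICD-9 code when the exact code string appears on ≥ 3 distinct calendar
dates in their record ("independent visits" read as distinct dates — an
encounter-identifier reading is not recoverable from date-stamped data).
Matching is exact-string; no hierarchy rollup or phecode grouping.
`case_counts_by_code` and `tabulate_codes_by_threshold` produce the
codes-per-threshold curve used to pick a case-count cutoff.

The synthetic record generator gives each patient a Bernoulli(prevalence)
carriage per code and carriers Poisson(visit_rate) coded visits on distinct
uniform dates over a 1996–2015 window, so the expected rule-of-three case
count is exactly n·prevalence·P(Poisson(rate) ≥ 3) — the test oracle.  The
default 12-code catalog spans prevalences 0.30 (routine exam V70.0) down to
0.01 (septicemia 038.9) with visit rates 1.5–8, mimicking the mix of
chronic frequently-coded and acute rarely-coded diagnoses in a regional
health system.  Real EHR data additionally have inter-patient visit-rate
heterogeneity, censored record spans and correlated comorbidity codes; the
generator models none of these, so it validates the counting procedure, not
any real phenome's case-count distribution.

## Known limitations

* Binary and quantitative effects are additive only; dominant/recessive or
  interaction models are not simulated.
* No covariates, environmental exposure or confounding; no rare-variant
  aggregation methods (the MAF grid bottoms out at 0.01).
* Wald-based tools will report slightly fewer extreme p-values than this
  package's LRT at small n (see above); at ≥ 1000 cases the difference is
  negligible.
* PLINK export writes synthetic chromosome/position placeholders; the files
  are for format interoperability, not genomic coordinates.
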