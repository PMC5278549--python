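# Methods

## The estimator

The package implements single-instrument Mendelian randomization by
two-stage regression. The instrument is the additive C-allele count of one
biallelic SNP; the exposure is serum triglyceride (mmol/L); the outcomes are
binary longevity (case-control), the continuous cumulative-deficit frailty
index FI ∈ [0, 1], and the binary Fried frailty phenotype (cross-sectional).

Stage 1 is OLS of exposure on allele count, fitted in the comparison group
for the case-control design and in the whole ageing arm for the
cross-sectional design. Its diagnostics are the overall regression F (the
square of the genotype t-statistic in the covariate-free fit; F > 10 is the
conventional weak-instrument gate) and R². Stage 2 regresses the outcome on
the stage-1 fitted values (logistic via IRLS for binary outcomes, OLS for
FI); its slope is the causal effect per 1 mmol/L genetically predicted
triglyceride. The identifying assumptions are the usual instrumental-variable
triple: the variant is (i) associated with the exposure, (ii) independent of
confounders — checked empirically by the genotype-covariate balance table —
and (iii) affects the outcome only through the exposure. Assumption (iii) is
untestable here; the variant's known weak HDL-C association is reported by
the genotype-lipid table but not modelled.

Covariate adjustment follows a fixed ladder: model 1 unadjusted; model 2 sex
(longevity) or age + sex (frailty); model 3 adds education, marital status,
smoking, drinking, BMI, and systolic/diastolic blood pressure; model 4 is a
bootstrap of model 2. Covariates enter stage 2 only by default (a stage-1
covariate list is exposed but empty by default): the original analysis does
not state which stage was adjusted, and stage-2-only adjustment leaves the
instrument-exposure equation — and hence the predicted exposure — identical
across models, which matches the way the printed per-allele estimates barely
move across models. Every model is complete-case within its own variable
set, and each estimate reports its own n.

### Standard errors and the bootstrap

Stage-2 standard errors are the naive second-stage ones, uncorrected for
first-stage estimation. That is deliberate: the reported intervals of the
original analysis are standard two-stage regression output, and its own
remedy — model 4 — is re-implemented here as a joint bootstrap: subjects are
resampled with replacement, both stages are re-fit per replicate (stage 1
within the replicate's comparison stratum), and the 95% CI is the percentile
interval of the replicate estimates (assumption-light and seed-reproducible;
the exact construction used originally is not documented). The point
estimate reported for model 4 is the full-sample two-stage estimate; p is a
normal approximation from the bootstrap SE on the estimation (log-odds or
slope) scale. Replicates that fail (separation, no genotype variation) are
dropped and counted in the output. Under the causal null the naive stage-2
test is asymptotically valid, which is why its type-I error calibrates to
~5% in the test suite.

### Wald ratio

For one instrument the two-stage estimate equals the ratio of the per-allele
outcome association to the per-allele exposure effect. The package exposes
this as `wald_ratio` with an optional first-order delta-method CI
(SE² = SE_GY²/β₁² + β_GY²·SE_β₁²/β₁⁴). For continuous outcomes without
covariates the identity is exact and is enforced at 1e-8 in the tests; for
logistic outcomes it holds to first order and is checked within simulation
tolerance.

## Genotype QC

Hardy-Weinberg equilibrium is tested by the 1-df goodness-of-fit χ² against
N·(p², 2pq, q²) with the allele frequency estimated from the sample and no
continuity correction — this convention reproduces the published p = 0.744
from the comparison-group counts, whereas a Yates-corrected test does not.
HWE is evaluated in the comparison group / ageing arm only, never in the
long-lived cases (selection can distort genotype proportions in cases
without invalidating the instrument). Monomorphic input degenerates to
χ² = 0, p = 1 with a warning rather than an error.

## Frailty scoring

FI is the mean of 45 deficits each in [0, 1]. With missing items the default
policy rescales the denominator to the number observed, provided at least
80% (36/45) of items are present, otherwise FI is missing; this is the
standard cumulative-deficit convention and is switchable to a strict
divide-by-45 policy. The Fried phenotype counts five criteria; ≥ 3 is frail.
Slowness is flagged when the timed up-and-go time is strictly above the
sex-specific 80th empirical percentile (linear interpolation) — the literal
reading of "below the 20th percentile in gait speed"; ties at the cutoff are
non-slow, so a degenerate all-equal stratum flags nobody. With missing
components the phenotype is called only when decidable: ≥ 3 observed-true →
frail, ≥ 3 observed-false → non-frail, otherwise missing. Deficit codebooks
(raw level → severity mappings) are user-supplied YAML; polychotomous items
default to equally spaced grades because only the 0-1 range of the mapping
is standardised, not its interior values.

## Grouped-summary reconstruction

Because the additive genotype takes only three values, count-weighted
regression of per-genotype means on allele count equals individual-level OLS
exactly (checked to 1e-10 against brute-force OLS). R² is the regression sum
of squares over between- plus within-group sums of squares, the within part
pooled from the published SDs as Σ n_g·sd_g² (population convention; the
(n_g−1) sample convention is available and indistinguishable at table sample
sizes), and F = (N−2)·R²/(1−R²). On the published triglyceride table this
yields slope 0.3025, R² 0.0403 and F 96.2 versus the printed 0.301, 0.040
and 95.3: the ~1% F excess is expected because the published fit excluded
subjects with missing lipids while the printed genotype counts do not say
which; the discrepancy is reported, not resolved.

## The synthetic-cohort generator

The generator emulates the statistical structure the estimator assumes, not
any real individuals.

* **Genotype**: allele count ~ Binomial(2, q) — HWE by construction;
  q = 0.291 (longevity arm) or 0.281 (ageing arm).
* **Exposure**: TG = 1.29 + 0.301·G + N(0, σ), with σ solved from
  β₁²·2q(1−q)/(β₁²·2q(1−q) + σ²) = R²_target, giving σ = 0.947 mmol/L at the
  default R² = 0.040. The model is kept strictly linear-Gaussian — draws are
  not truncated at zero even though ~9% fall non-positive — because
  truncation attenuates the per-allele slope and breaks parameter recovery;
  real triglyceride distributions are right-skewed and strictly positive,
  which this generator does not reproduce.
* **Longevity**: cases are rejection-sampled with acceptance probability
  expit(α + λ·TG), λ = ln(0.61) per mmol/L by default, α anchored to a 30%
  base rate at the population-mean TG. Setting λ = 0 makes genotype and case
  status independent. A draw budget guards against configurations with
  vanishing acceptance.
* **Ageing arm**: a latent mean deficit level m = 0.10 + β_FI·TG + N(0, 0.04)
  (clipped to [0, 0.95]) parameterises a per-subject Beta(m·k, (1−m)·k)
  deficit probability (k = 30); 36 items are Bernoulli and 9 are 5-level
  graded draws with that probability, so the scored FI is unbiased for the
  latent level and regression of FI on TG recovers β_FI (default 0.007, the
  observational slope scale). Fried components share a standard-normal
  per-subject vulnerability factor (loading 1.0 on each logit, 0.08 on
  log gait time) plus a TG term with slope ln(1.91) by default — anchored to
  the printed causal phenotype OR since no generative value is stated; the
  induced phenotype-level slope is of the same order but not calibrated to
  it. Marginal component frequencies (8/15/6/20% and a 20% slowness rule)
  give a frail fraction around 7-9%.
* **Covariates** are drawn independently of genotype from per-arm marginal
  distributions matching the published descriptive tables — encoding, by
  construction, the balance assumption the analysis verifies. They are
  *marginals only*: the real joint covariate structure (age-BMI correlation,
  sex-smoking association, …) is not reproduced, so passing tests says
  nothing about covariate-adjustment behaviour under realistic collinearity.
* **Reproducibility**: one integer seed; each generator function derives its
  own deterministic stream, so cohorts are byte-identical across runs for a
  fixed seed.

## Numerical choices

Logistic fits use binomial-GLM IRLS with tolerance 1e-8 and at most 100
iterations; non-convergence, |coefficient| > 30 or SE > 1e3 raise a
convergence error flagged as (quasi-)separation. A constant predicted
exposure (exact, by `ptp == 0`, not a variance tolerance) or a single
outcome class raises a no-estimate error rather than returning garbage.
Zero cells in the allelic 2×2 table get the Haldane-Anscombe 0.5 correction,
flagged in the result. Kruskal-Wallis on identical-distribution groups
returns statistic 0 / p 1 (the all-tied case is special-cased). Significance
is reported two-sided at 0.05 with no multiple-testing correction, matching
the original analysis; this is a documented limitation, not an endorsement.

## Problem sizes

The test suite uses the design's own cohort sizes (2294 / 438 / 1750) for
single-cohort checks; replicate studies use 200 replicates for stage-1
recovery and type-I error calibration, and 200 replicates × B = 200
bootstrap resamples at n = 500 for the coverage study — sizes chosen so
Monte-Carlo error bands (3 SD, binomial) are tight enough to be informative.

## Known limitations

* One instrument only: no IVW/MR-Egger/median multi-SNP estimators, and no
  pleiotropy modelling beyond reporting the genotype-HDL-C association.
* The generator's exposure can be non-positive and its covariates are
  independent marginals; neither matches real lipid data.
* Naive stage-2 SEs understate uncertainty relative to correctly propagated
  two-stage variance; use model 4 when that matters.
* The Fried phenotype's causal slope parameter acts at the component level;
  the induced phenotype-level log-OR is only approximately that value.
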