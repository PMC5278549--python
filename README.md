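# lipidmr

Single-instrument Mendelian randomization (MR) of serum triglycerides against
two ageing phenotypes — longevity and frailty — with everything needed to run
the analysis end to end on individual-level cohort data or on synthetic
cohorts that emulate the original two-arm design.

## Who this is for

Epidemiologists and biostatisticians who want a tested, reproducible
implementation of the classic one-SNP MR workflow applied to ageing
outcomes: an *APOA5*-region variant (rs662799, additive C-allele coding) as
the instrument for triglyceride concentration; a case-control arm with
long-lived individuals versus an elderly comparison group; and a
cross-sectional ageing arm scored for the 45-item cumulative-deficit frailty
index (FI) and the modified Fried frailty phenotype.

## The method

Stage 1 regresses the exposure on the allele count in the comparison group,

    TG_i = β₀ + β₁ G_i + ε_i,      G_i ∈ {0, 1, 2},

reporting β₁ (mmol/L per C allele), the overall F (weak-instrument rule
F > 10) and R². Stage 2 regresses the outcome on the genetically predicted
exposure TĜ_i = β₀ + β₁G_i — logistic for longevity and the Fried phenotype
(odds ratio per 1 mmol/L), OLS for the FI (FI units per mmol/L):

    logit P(Y_i = 1) = α₀ + α₁ TĜ_i + γᵀz_i .

α₁ is the causal effect estimate. The single-instrument Wald identity
α₁ = (per-allele outcome effect) / β₁ is exposed as a cross-check and holds
exactly for continuous outcomes without covariates. Four adjustment models
mirror the study: (1) unadjusted, (2) sex — plus age for frailty, (3)
additionally education, marital status, smoking, drinking, BMI, and systolic
/ diastolic blood pressure, (4) a joint bootstrap of model 2 (both stages
re-fit per resample, percentile 95% CI). Instrument validity diagnostics —
Hardy–Weinberg equilibrium (1-df χ², no continuity correction) and covariate
balance across genotypes (χ² / Kruskal–Wallis) — are built in, as is
reconstruction of stage-1 statistics from published per-genotype
(n, mean, SD) tables.

## Worked example

Reconstruct the stage-1 fit from a published genotype-by-triglyceride table
and cross-check the causal OR with the Wald identity:

```
$ cat grouped.csv
genotype,n,mean,sd
TT,1150,1.29,0.82
TC,953,1.46,0.86
CC,191,2.09,1.70

$ lipidmr reconstruct --summary-file grouped.csv --or-gy 0.86
slope 0.3025 mmol/L per allele; R2 0.0403; F 96.2; n 2294
Wald causal OR 0.607 per 1 mmol/L
```

The slope says each C allele raises triglycerides by ~0.30 mmol/L; the
instrument explains ~4% of triglyceride variance (F ≈ 96 ≫ 10, so weak-
instrument bias is not a concern); and a per-allele longevity OR of 0.86
converts to a causal OR of ~0.61 per 1 mmol/L of genetically predicted
triglyceride.

The same works in Python, together with genotype QC:

```python
>>> import lipidmr as lm
>>> counts = lm.GenotypeCounts(1150, 953, 191)
>>> lm.allele_frequencies(counts)[1]      # C-allele frequency
0.29097646033129904
>>> lm.hwe_test(counts).p                 # Hardy-Weinberg equilibrium
0.7440051777532547
```

A full synthetic run of either design (simulate → QC → score → MR → report):

```
lipidmr mr --design longevity-case-control --seed 5 --out-dir run1
lipidmr mr --design frailty-cross-sectional --seed 5 --out-dir run2
lipidmr report --results-dir run1
```

`run1/estimates.csv` holds one row per (model, method): the per-allele
reduced-form OR, the two-stage causal estimate, and the observational
association, each with 95% CI, p, and the complete-case n.

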