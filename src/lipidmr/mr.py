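"""Single-instrument Mendelian randomization by two-stage regression.

Stage 1 regresses the exposure (serum triglyceride, mmol/L) on the additive
allele count of the instrument SNP by OLS and reports the weak-instrument
diagnostics (overall F, R^2; F > 10 is the conventional adequacy rule).
Stage 2 regresses the outcome on the stage-1 predicted exposure — logistic
regression for a binary outcome (longevity, Fried frailty), OLS for the
continuous frailty index — so the stage-2 coefficient is the causal effect per
1 mmol/L of genetically predicted triglyceride.

The adjustment ladder mirrors the study design: model 1 unadjusted; model 2
sex (longevity) or age + sex (frailty); model 3 additionally education,
marital status, smoking, drinking, BMI, and blood pressures; model 4 is a
joint (both stages re-fit per replicate) bootstrap of model 2 with a
percentile CI. Stage-2 standard errors are the naive second-stage ones,
uncorrected for first-stage estimation; the bootstrap is the remedy offered
for that. Every model is complete-case within its own variable set, and the
Wald ratio (reduced-form effect divided by the stage-1 beta) is exposed as an
explicit cross-check: with a continuous outcome and no covariates it equals
the two-stage estimate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .genetics import code_genotype

WEAK_INSTRUMENT_F = 10.0
LOGIT_TOL = 1e-8
LOGIT_MAXITER = 100
_Z95 = stats.norm.ppf(0.975)

# adjustment ladder; model 4 re-uses model 2's covariates under the bootstrap
MODEL_EXTRA = ["illiterate", "currently_married", "regular_smoker", "regular_drinker", "bmi", "sbp", "dbp"]
MODEL_COVARIATES = {
    "longevity": {1: [], 2: ["sex"], 3: ["sex"] + MODEL_EXTRA, 4: ["sex"]},
    "frailty": {1: [], 2: ["age", "sex"], 3: ["age", "sex"] + MODEL_EXTRA, 4: ["age", "sex"]},
}


class SingularDesignError(ValueError):
    """Raised when the instrument (or design) has no variation."""


class NoEstimateError(ValueError):
    """Raised when the stage-2 predictor is degenerate (constant)."""


class ConvergenceError(RuntimeError):
    """Raised on logistic non-convergence or (quasi-)separation."""


@dataclass(frozen=True)
class Stage1Result:
    """Instrument-on-exposure regression: beta (mmol/L per C allele), naive SE,
    intercept, overall regression F, R^2, and the complete-case n used."""

    beta: float
    se: float
    intercept: float
    f_stat: float
    r2: float
    n: int

    @property
    def weak_instrument(self) -> bool:
        return self.f_stat <= WEAK_INSTRUMENT_F


@dataclass(frozen=True)
class CausalEstimate:
    """One estimate on its reporting scale.

    For binary outcomes point/ci are odds ratios per 1 mmol/L (scale
    'log-odds per mmol/L', exponentiated for reporting); for the FI they are
    slopes in FI units per mmol/L.
    """

    scale: str
    point: float
    ci_low: float
    ci_high: float
    p: float
    method: str  # two-stage | wald-ratio | bootstrap-two-stage | observational | reduced-form
    model_id: int
    n: int
    n_dropped_replicates: int = 0


def design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design: sex -> female indicator, booleans -> 0/1."""
    cols = {}
    for c in covariates:
        s = cohort[c]
        if c == "sex":
            cols["sex_female"] = s.map({"female": 1.0, "male": 0.0, 1: 1.0, 0: 0.0})
        elif s.dtype == bool:
            cols[c] = s.astype(float)
        else:
            cols[c] = pd.to_numeric(s, errors="coerce")
    return pd.DataFrame(cols, index=cohort.index)


def stage1_fit(
    cohort: pd.DataFrame,
    exposure: str = "triglyceride",
    covariates=(),
    genotype_col: str = "genotype",
) -> Stage1Result:
    """OLS of the exposure on the additive allele count (plus covariates).

    Complete-case within {exposure, genotype, covariates}. The reported F is
    the overall regression F; for the covariate-free fit it equals the square
    of the genotype t-statistic.
    """
    g = code_genotype(cohort[genotype_col], "additive")["g_additive"]
    X = pd.concat([g, design_matrix(cohort, covariates)], axis=1)
    y = pd.to_numeric(cohort[exposure], errors="coerce")
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask]
    if len(y) < 3:
        raise SingularDesignError(f"need >= 3 complete cases, got {len(y)}")
    if X["g_additive"].nunique() < 2:
        raise SingularDesignError("no genotype variation in the stage-1 sample")
    if float(np.var(y)) == 0.0:
        return Stage1Result(beta=0.0, se=0.0, intercept=float(y.iloc[0]), f_stat=0.0, r2=0.0, n=len(y))
    res = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
    f = float(res.fvalue)
    return Stage1Result(
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        intercept=float(res.params[0]),
        f_stat=0.0 if np.isnan(f) else f,
        r2=float(res.rsquared),
        n=int(res.nobs),
    )


def predict_exposure(stage1: Stage1Result, cohort: pd.DataFrame, genotype_col: str = "genotype") -> pd.Series:
    """Genetically predicted exposure: intercept + beta * allele count.

    Takes at most three distinct values; missing genotype -> missing
    prediction (the subject drops out of downstream complete-case fits).
    """
    g = code_genotype(cohort[genotype_col], "additive")["g_additive"]
    return stage1.intercept + stage1.beta * g


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """Binomial GLM by IRLS (tol 1e-8, max 100 iterations) with separation checks."""
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=LOGIT_MAXITER, tol=LOGIT_TOL)
    except PerfectSeparationError as exc:  # pragma: no cover - statsmodels version dependent
        raise ConvergenceError(f"perfect separation in logistic fit: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(f"IRLS did not converge in {LOGIT_MAXITER} iterations")
    if np.any(np.abs(res.params) > 30) or np.any(res.bse > 1e3):
        raise ConvergenceError(
            "logistic fit diagnostics indicate (quasi-)separation: "
            f"max|beta|={np.max(np.abs(res.params)):.3g}, max SE={np.max(res.bse):.3g}"
        )
    return res


def _stage2_frame(cohort, predicted, outcome, covariates):
    Z = design_matrix(cohort, covariates)
    y = pd.to_numeric(cohort[outcome], errors="coerce") if isinstance(outcome, str) else pd.Series(outcome, index=cohort.index)
    x = pd.Series(predicted, index=cohort.index, dtype=float)
    mask = x.notna() & y.notna() & (Z.notna().all(axis=1) if len(Z.columns) else True)
    return x[mask].to_numpy(), y[mask].to_numpy(dtype=float), Z[mask].to_numpy(), int(mask.sum())


def stage2_binary(cohort, predicted, outcome, covariates=(), model_id: int = 1, method: str = "two-stage") -> CausalEstimate:
    """Logistic regression of a binary outcome on the predicted exposure.

    Reports the OR per 1 mmol/L with Wald 95% CI and p (naive second-stage SE).
    """
    x, y, Z, n = _stage2_frame(cohort, predicted, outcome, covariates)
    if n == 0 or np.ptp(x) == 0.0:
        raise NoEstimateError("predicted exposure is constant in the stage-2 sample")
    if len(np.unique(y)) < 2:
        raise NoEstimateError("both outcome classes must be present")
    X = sm.add_constant(np.column_stack([x, Z]) if Z.size else x.reshape(-1, 1))
    res = _fit_logistic(y, X)
    b, se = float(res.params[1]), float(res.bse[1])
    return CausalEstimate(
        scale="log-odds per mmol/L",
        point=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z95 * se)),
        ci_high=float(np.exp(b + _Z95 * se)),
        p=float(2 * stats.norm.sf(abs(b) / se)),
        method=method,
        model_id=model_id,
        n=n,
    )


def stage2_continuous(cohort, predicted, outcome, covariates=(), model_id: int = 1, method: str = "two-stage") -> CausalEstimate:
    """OLS of the continuous outcome (FI) on the predicted exposure."""
    x, y, Z, n = _stage2_frame(cohort, predicted, outcome, covariates)
    if n == 0 or np.ptp(x) == 0.0:
        raise NoEstimateError("predicted exposure is constant in the stage-2 sample")
    X = sm.add_constant(np.column_stack([x, Z]) if Z.size else x.reshape(-1, 1))
    res = sm.OLS(y, X).fit()
    b, se = float(res.params[1]), float(res.bse[1])
    ci = res.conf_int()[1]
    return CausalEstimate(
        scale="FI-units per mmol/L",
        point=b,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues[1]),
        method=method,
        model_id=model_id,
        n=n,
    )


def two_stage(
    cohort: pd.DataFrame,
    outcome: str,
    binary: bool,
    model_id: int = 1,
    design: str = "longevity",
    stage1_cohort: pd.DataFrame | None = None,
    exposure: str = "triglyceride",
    covariates=None,
    stage1_covariates=(),
) -> tuple[Stage1Result, CausalEstimate]:
    """Full two-stage MR: stage 1 (optionally in a designated sub-cohort, e.g.
    the comparison group of a case-control design), prediction, stage 2.

    Covariates default to the model-`model_id` ladder for the given design and
    enter stage 2 only; stage-1 adjustment is available via stage1_covariates.
    """
    if covariates is None:
        covariates = MODEL_COVARIATES[design][model_id]
    s1 = stage1_fit(stage1_cohort if stage1_cohort is not None else cohort, exposure=exposure, covariates=stage1_covariates)
    xhat = predict_exposure(s1, cohort)
    fit = stage2_binary if binary else stage2_continuous
    return s1, fit(cohort, xhat, outcome, covariates=covariates, model_id=model_id)


def wald_ratio(
    assoc_gy: float,
    stage1_beta: float,
    binary: bool = True,
    se_gy: float | None = None,
    se_stage1: float | None = None,
    n: int = 0,
    model_id: int = 1,
) -> CausalEstimate:
    """Single-instrument Wald ratio: causal effect = per-allele outcome effect
    divided by the per-allele exposure effect.

    `assoc_gy` is on the log-odds scale for a binary outcome (so the causal OR
    is OR_GY ** (1 / stage1_beta)). When both SEs are given, a first-order
    delta-method 95% CI and p accompany the point estimate.
    """
    if stage1_beta == 0:
        raise ZeroDivisionError("Wald ratio undefined: stage-1 beta is zero")
    ratio = assoc_gy / stage1_beta
    se = p = np.nan
    if se_gy is not None and se_stage1 is not None:
        se = np.sqrt(se_gy**2 / stage1_beta**2 + assoc_gy**2 * se_stage1**2 / stage1_beta**4)
        p = float(2 * stats.norm.sf(abs(ratio) / se)) if se > 0 else np.nan
    lo, hi = ratio - _Z95 * se, ratio + _Z95 * se
    if binary:
        point, lo, hi = np.exp(ratio), np.exp(lo), np.exp(hi)
        scale = "log-odds per mmol/L"
    else:
        point, scale = ratio, "FI-units per mmol/L"
    return CausalEstimate(
        scale=scale, point=float(point), ci_low=float(lo), ci_high=float(hi),
        p=p, method="wald-ratio", model_id=model_id, n=n,
    )


def bootstrap_mr(
    cohort: pd.DataFrame,
    outcome: str,
    binary: bool,
    B: int = 1000,
    seed: int = 0,
    model_id: int = 4,
    design: str = "longevity",
    stage1_mask: pd.Series | None = None,
    exposure: str = "triglyceride",
    covariates=None,
    stage1_covariates=(),
) -> CausalEstimate:
    """Joint bootstrap of the two-stage estimator (internal validation).

    Subjects are resampled with replacement; each replicate re-fits stage 1
    (within the resampled stage-1 stratum, e.g. controls) and stage 2. The
    point estimate is the full-sample two-stage estimate; the 95% CI is the
    percentile interval of the replicate estimates and p is a normal
    approximation from the bootstrap SE on the estimation scale.
    Non-convergent replicates are dropped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if covariates is None:
        covariates = MODEL_COVARIATES[design][min(model_id, 3) if model_id != 4 else 2]
    mask = pd.Series(True, index=cohort.index) if stage1_mask is None else stage1_mask.astype(bool)

    def _estimate(df, m):
        s1 = stage1_fit(df[m], exposure=exposure, covariates=stage1_covariates)
        xhat = predict_exposure(s1, df)
        fit = stage2_binary if binary else stage2_continuous
        est = fit(df, xhat, outcome, covariates=covariates, model_id=model_id)
        return np.log(est.point) if binary else est.point, est

    theta_full, est_full = _estimate(cohort, mask.to_numpy())
    rng = np.random.default_rng(seed)
    idx_all = np.arange(len(cohort))
    reps = []
    dropped = 0
    for _ in range(B):
        take = rng.choice(idx_all, size=len(idx_all), replace=True)
        df = cohort.iloc[take]
        try:
            theta, _ = _estimate(df.reset_index(drop=True), mask.to_numpy()[take])
        except (SingularDesignError, NoEstimateError, ConvergenceError, ZeroDivisionError):
            dropped += 1
            continue
        reps.append(theta)
    if not reps:
        raise ConvergenceError(f"all {B} bootstrap replicates failed")
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    sd = float(reps.std(ddof=1)) if len(reps) > 1 else np.nan
    p = float(2 * stats.norm.sf(abs(theta_full) / sd)) if sd and sd > 0 else np.nan
    if binary:
        point, lo, hi = np.exp(theta_full), np.exp(lo), np.exp(hi)
    else:
        point = theta_full
    return CausalEstimate(
        scale=est_full.scale,
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        method="bootstrap-two-stage",
        model_id=model_id,
        n=est_full.n,
        n_dropped_replicates=dropped,
    )


def observational_assoc(
    cohort: pd.DataFrame,
    outcome: str,
    binary: bool,
    exposure: str = "triglyceride",
    covariates=None,
    model_id: int = 1,
    design: str = "longevity",
) -> CausalEstimate:
    """Conventional (confoundable) regression of the outcome on the MEASURED
    exposure — the observational counterpart the MR estimate is contrasted with."""
    if covariates is None:
        covariates = MODEL_COVARIATES[design][model_id]
    x = pd.to_numeric(cohort[exposure], errors="coerce")
    fit = stage2_binary if binary else stage2_continuous
    est = fit(cohort, x, outcome, covariates=covariates, model_id=model_id, method="observational")
    return est


def reduced_form(
    cohort: pd.DataFrame,
    outcome: str,
    binary: bool,
    covariates=(),
    model_id: int = 1,
) -> CausalEstimate:
    """Per-allele (instrument-on-outcome) association — the reduced form whose
    ratio to the stage-1 beta is the Wald estimate."""
    g = code_genotype(cohort["genotype"], "additive")["g_additive"]
    fit = stage2_binary if binary else stage2_continuous
    est = fit(cohort, g, outcome, covariates=covariates, model_id=model_id, method="reduced-form")
    scale = "log-odds per C allele" if binary else "outcome units per C allele"
    return replace(est, scale=scale)


def confounder_balance(cohort: pd.DataFrame, covariates, genotype_col: str = "genotype") -> pd.DataFrame:
    """Covariate balance across TT/TC/CC: chi-squared for categorical
    covariates, Kruskal-Wallis for continuous ones; two-sided p per row."""
    g = code_genotype(cohort[genotype_col], "additive")["g_additive"]
    rows = []
    for cov in covariates:
        s = cohort[cov]
        mask = s.notna() & g.notna()
        if mask.sum() == 0:
            rows.append({"covariate": cov, "test": "missing", "statistic": np.nan, "p": np.nan, "n": 0})
            continue
        sv, gv = s[mask], g[mask]
        categorical = sv.dtype == bool or sv.dtype == object or sv.nunique() <= 2
        if categorical:
            table = pd.crosstab(sv, gv)
            stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            test = "chi-squared"
        else:
            groups = [pd.to_numeric(sv[gv == k]).to_numpy() for k in (0, 1, 2) if (gv == k).any()]
            if len(groups) < 2:
                rows.append({"covariate": cov, "test": "missing", "statistic": np.nan, "p": np.nan, "n": int(mask.sum())})
                continue
            flat = np.concatenate(groups)
            if np.all(flat == flat[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.kruskal(*groups)
            test = "kruskal-wallis"
        rows.append({"covariate": cov, "test": test, "statistic": float(stat), "p": float(p), "n": int(mask.sum())})
    return pd.DataFrame(rows)
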