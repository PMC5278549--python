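"""Synthetic two-arm cohort generator.

Emulates the statistical structure the MR analysis assumes, so every
downstream stage is testable without the (non-public) study data:

* a case-control longevity arm — long-lived cases vs an elderly comparison
  group, genotypes drawn under Hardy-Weinberg equilibrium, triglyceride
  linear in allele count with a residual SD calibrated so the population
  instrument R^2 hits a target, and case status following a logistic model in
  triglyceride whose slope is the switchable causal effect;
* a cross-sectional ageing arm — the same genotype/exposure model plus a
  latent frailty level, linear in triglyceride, realised through 45 item-level
  deficits (so the frailty-index scorer is exercised end to end) and five
  Fried components with a shared per-subject vulnerability factor.

Defaults are the study conditions: per-allele triglyceride effect
0.301 mmol/L, instrument R^2 0.040, C-allele frequency 0.291 (longevity arm)
/ 0.281 (ageing arm), 438 cases / 2294 comparison subjects / 1750 ageing-arm
subjects. Covariates are generated independent of genotype — the
instrument-validity assumption the balance table verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .frailty import DEFICIT_COLUMNS, N_DEFICITS

# ---------------------------------------------------------------------------
# generator constants (ageing-arm frailty structure)
# ---------------------------------------------------------------------------
FI_CONCENTRATION = 30.0     # beta-distribution concentration of per-subject deficit probability
N_GRADED_DEFICITS = 9       # last 9 items are 5-level graded, the rest dichotomous
FRIED_MARGINALS = {"weight_loss": 0.08, "exhaustion": 0.15, "low_activity": 0.06, "weakness": 0.20}
FRIED_SHARED_LOADING = 1.0  # loading of the shared vulnerability factor on each component logit
GAIT_LOG_MEAN = {"male": np.log(9.5), "female": np.log(10.5)}  # seconds, timed up-and-go
GAIT_SHARED_LOADING = 0.08
GAIT_LOG_NOISE_SD = 0.15
# acceptance probability at the population-mean triglyceride; longevity (95+)
# is a rare outcome, and rarity is what lets the conditional logistic slope
# survive marginalisation (population controls then approximate non-cases)
CASE_BASE_RATE = 0.05
SAMPLING_BUDGET_FACTOR = 200  # max candidate draws per requested case

# per-allele effects on the other lipids (reported genotype-lipid associations)
HDL_BETA, HDL_TT_MEAN, HDL_SD = -0.067, 1.48, 0.33
LDL_BETA, LDL_TT_MEAN, LDL_SD = 0.042, 2.78, 0.75


class DegenerateParameterError(ValueError):
    """Raised when (beta_GX, target_R2) admit no residual SD."""


class SamplingBudgetError(RuntimeError):
    """Raised when rejection sampling of cases exceeds its draw budget."""


def _default_covariate_spec() -> dict:
    """Marginal covariate distributions per arm (independent of genotype).

    Values follow the published descriptive statistics of the two arms:
    the comparison group (elderly controls) and the long-lived cases differ in
    literacy, marital status, smoking/drinking, BMI and blood pressure; the
    ageing arm (70-84 y) reuses the comparison-group margins with a uniform
    age range.
    """
    comparison = {
        "age": ("normal", 70.6, 5.3),
        "sex": ("female", 0.623),
        "illiterate": ("bernoulli", 0.512),
        "currently_married": ("bernoulli", 0.730),
        "regular_smoker": ("bernoulli", 0.266),
        "regular_drinker": ("bernoulli", 0.298),
        "bmi": ("normal", 24.1, 3.4),
        "sbp": ("normal", 148.1, 25.0),
        "dbp": ("normal", 82.0, 13.1),
    }
    case = {
        "age": ("normal", 97.4, 2.1),
        "sex": ("female", 0.783),
        "illiterate": ("bernoulli", 0.820),
        "currently_married": ("bernoulli", 0.052),
        "regular_smoker": ("bernoulli", 0.196),
        "regular_drinker": ("bernoulli", 0.385),
        "bmi": ("normal", 21.5, 4.2),
        "sbp": ("normal", 136.7, 22.9),
        "dbp": ("normal", 80.1, 11.0),
    }
    ageing = dict(comparison)
    ageing["age"] = ("uniform", 70.0, 84.0)
    return {"comparison": comparison, "case": case, "ageing": ageing}


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generator; defaults are the study conditions."""

    q_C: float = 0.291                      # C-allele frequency
    beta_GX: float = 0.301                  # mmol/L triglyceride per C allele
    target_R2: float = 0.040                # population instrument R^2
    tg_mean_TT: float = 1.29                # mmol/L triglyceride mean in TT carriers
    causal_logOR_longevity: float = float(np.log(0.61))  # log-odds of longevity per mmol/L
    causal_beta_FI: float = 0.007           # FI units per mmol/L
    causal_logOR_frailty: float = float(np.log(1.91))    # log-odds of Fried frailty per mmol/L
    n_cases: int = 438
    n_controls: int = 2294
    n_ageing: int = 1750
    fi_baseline: float = 0.10               # latent mean FI at triglyceride 0
    fi_noise_sd: float = 0.04               # SD of the latent FI around its linear predictor
    covariate_spec: dict = field(default_factory=_default_covariate_spec)
    null_residual_sd: float = 0.95          # mmol/L; used only when beta_GX = target_R2 = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_C <= 1.0):
            raise ValueError(f"q_C must lie in [0, 1], got {self.q_C}")
        if not (0.0 <= self.target_R2 < 1.0):
            raise DegenerateParameterError(f"target_R2 must lie in [0, 1), got {self.target_R2}")
        for name in ("n_cases", "n_controls", "n_ageing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.null_residual_sd <= 0:
            raise ValueError("null_residual_sd must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def default_longevity_params(seed: int = 0, **overrides) -> SimulationParams:
    """Case-control arm defaults (C-allele frequency 0.291, 438/2294)."""
    return replace(SimulationParams(seed=seed), **overrides)


def default_ageing_params(seed: int = 0, **overrides) -> SimulationParams:
    """Cross-sectional ageing-arm defaults (C-allele frequency 0.281, n=1750)."""
    base = SimulationParams(q_C=0.281, seed=seed)
    return replace(base, **overrides)


def derive_residual_sd(params: SimulationParams) -> float:
    """Residual triglyceride SD sigma such that the population instrument R^2
    equals target_R2: beta^2 * 2q(1-q) / (beta^2 * 2q(1-q) + sigma^2) = R^2,
    using Var(genotype) = 2q(1-q) under HWE.
    """
    if params.target_R2 >= 1.0:
        raise DegenerateParameterError("target_R2 >= 1 admits no positive residual SD")
    if params.target_R2 == 0.0:
        if params.beta_GX == 0.0:
            return params.null_residual_sd  # pure noise; any sigma > 0 is consistent
        raise DegenerateParameterError("target_R2 = 0 with a nonzero beta_GX requires infinite noise")
    if params.beta_GX == 0.0 or params.q_C in (0.0, 1.0):
        raise DegenerateParameterError("nonzero target_R2 requires beta_GX != 0 and 0 < q_C < 1")
    var_g = 2.0 * params.q_C * (1.0 - params.q_C)
    explained = params.beta_GX**2 * var_g
    return float(np.sqrt(explained * (1.0 - params.target_R2) / params.target_R2))


# ---------------------------------------------------------------------------
# drawing blocks
# ---------------------------------------------------------------------------

def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # distinct deterministic stream per generator function
    return np.random.default_rng([stream, params.seed])


def _draw_covariates(rng: np.random.Generator, n: int, spec: dict) -> dict:
    out = {}
    for name, dist in spec.items():
        kind = dist[0]
        if kind == "normal":
            out[name] = rng.normal(dist[1], dist[2], size=n)
        elif kind == "uniform":
            out[name] = rng.uniform(dist[1], dist[2], size=n)
        elif kind == "bernoulli":
            out[name] = rng.random(n) < dist[1]
        elif kind == "female":
            out[name] = np.where(rng.random(n) < dist[1], "female", "male")
        else:
            raise ValueError(f"unknown covariate distribution kind {kind!r}")
    return out


def _draw_genotype(rng: np.random.Generator, n: int, q: float) -> np.ndarray:
    return rng.binomial(2, q, size=n).astype(float)  # HWE: allele count ~ Binomial(2, q)


def _draw_lipids(rng: np.random.Generator, g: np.ndarray, params: SimulationParams, sigma: float):
    # kept strictly linear-Gaussian (no truncation at zero): truncating would
    # attenuate the per-allele slope the downstream estimator must recover
    tg = params.tg_mean_TT + params.beta_GX * g + rng.normal(0.0, sigma, size=len(g))
    hdl = HDL_TT_MEAN + HDL_BETA * g + rng.normal(0.0, HDL_SD, size=len(g))
    ldl = LDL_TT_MEAN + LDL_BETA * g + rng.normal(0.0, LDL_SD, size=len(g))
    return tg, hdl, ldl


def _assemble(prefix: str, arm: str, cov: dict, g, tg, hdl, ldl) -> pd.DataFrame:
    n = len(g)
    df = pd.DataFrame({"id": [f"{prefix}-{i + 1:06d}" for i in range(n)], "arm": arm})
    for name, vals in cov.items():
        if np.asarray(vals).dtype == bool:
            df[name] = np.asarray(vals).astype(int)
        else:
            df[name] = vals
    df["genotype"] = g
    df["triglyceride"] = tg
    df["hdl_c"] = hdl
    df["ldl_c"] = ldl
    return df


def generate_comparison_cohort(params: SimulationParams) -> pd.DataFrame:
    """The elderly comparison group: genotypes under HWE at q_C, triglyceride
    = tg_mean_TT + beta_GX * genotype + Normal(0, sigma), covariates from
    covariate_spec, fully reproducible for a fixed seed."""
    rng = _rng(params, 1)
    n = params.n_controls
    sigma = derive_residual_sd(params)
    g = _draw_genotype(rng, n, params.q_C)
    tg, hdl, ldl = _draw_lipids(rng, g, params, sigma)
    cov = _draw_covariates(rng, n, params.covariate_spec["comparison"])
    df = _assemble("cmp", "comparison", cov, g, tg, hdl, ldl)
    df["longevity"] = 0
    return df


def generate_longevity_case_control(params: SimulationParams) -> pd.DataFrame:
    """Cases plus comparison subjects for the case-control longevity design.

    Cases are rejection-sampled from a source population in which
    P(longevity) is logistic in triglyceride with slope
    causal_logOR_longevity (anchored to acceptance CASE_BASE_RATE at the
    population-mean triglyceride). Under a zero slope, genotype is
    independent of case status by construction.
    """
    controls = generate_comparison_cohort(params)
    rng = _rng(params, 2)
    sigma = derive_residual_sd(params)
    lam = params.causal_logOR_longevity
    tg_ref = params.tg_mean_TT + params.beta_GX * 2 * params.q_C
    alpha = np.log(CASE_BASE_RATE / (1 - CASE_BASE_RATE)) - lam * tg_ref

    kept = []
    n_kept = 0
    budget = SAMPLING_BUDGET_FACTOR * max(params.n_cases, 1)
    drawn = 0
    while n_kept < params.n_cases:
        chunk = min(4 * max(params.n_cases - n_kept, 256), budget - drawn)
        if chunk <= 0:
            raise SamplingBudgetError(
                f"case sampling exhausted its budget of {budget} draws "
                f"({n_kept}/{params.n_cases} cases accepted); the longevity slope is too extreme"
            )
        g = _draw_genotype(rng, chunk, params.q_C)
        tg, hdl, ldl = _draw_lipids(rng, g, params, sigma)
        p_case = expit(alpha + lam * tg)
        accept = rng.random(chunk) < p_case
        drawn += chunk
        if accept.any():
            kept.append(np.column_stack([g[accept], tg[accept], hdl[accept], ldl[accept]]))
            n_kept += int(accept.sum())

    if params.n_cases > 0:
        block = np.concatenate(kept, axis=0)[: params.n_cases]
        cov = _draw_covariates(rng, params.n_cases, params.covariate_spec["case"])
        cases = _assemble("lli", "longevity-case", cov, block[:, 0], block[:, 1], block[:, 2], block[:, 3])
        cases["longevity"] = 1
    else:
        cases = controls.iloc[0:0].copy()
    return pd.concat([cases, controls], ignore_index=True)


def generate_ageing_cohort(params: SimulationParams) -> pd.DataFrame:
    """The cross-sectional ageing arm with 45 deficits and 5 Fried components.

    A latent mean deficit level m_i = fi_baseline + causal_beta_FI * TG_i +
    noise is realised through a per-subject Beta(m*k, (1-m)*k) deficit
    probability; items are Bernoulli (dichotomous) or scaled-binomial
    (graded) draws with that probability, so the scored FI is unbiased for
    the latent level and regression of FI on triglyceride recovers
    causal_beta_FI. Fried components share a per-subject vulnerability factor
    and depend on triglyceride on the logit scale with slope
    causal_logOR_frailty; gait time is log-normal with a sex-specific mean.
    """
    rng = _rng(params, 3)
    n = params.n_ageing
    sigma = derive_residual_sd(params)
    g = _draw_genotype(rng, n, params.q_C)
    tg, hdl, ldl = _draw_lipids(rng, g, params, sigma)
    cov = _draw_covariates(rng, n, params.covariate_spec["ageing"])
    df = _assemble("age", "ageing", cov, g, tg, hdl, ldl)

    noise = rng.normal(0, params.fi_noise_sd, n) if params.fi_noise_sd > 0 else 0.0
    m = np.clip(params.fi_baseline + params.causal_beta_FI * tg + noise, 0.0, 0.95)
    p_subject = np.where(m > 0, rng.beta(np.maximum(m, 1e-12) * FI_CONCENTRATION, (1 - m) * FI_CONCENTRATION), 0.0)
    n_dich = N_DEFICITS - N_GRADED_DEFICITS
    deficits = np.empty((n, N_DEFICITS))
    deficits[:, :n_dich] = rng.random((n, n_dich)) < p_subject[:, None]
    # graded items: 5 equally spaced severity levels with the same mean
    deficits[:, n_dich:] = rng.binomial(4, p_subject[:, None], size=(n, N_GRADED_DEFICITS)) / 4.0
    for j, col in enumerate(DEFICIT_COLUMNS):
        df[col] = deficits[:, j]

    u = rng.normal(0.0, 1.0, n)  # shared vulnerability factor
    tg_centred = tg - tg.mean()
    for name, p0 in FRIED_MARGINALS.items():
        logit = np.log(p0 / (1 - p0)) + params.causal_logOR_frailty * tg_centred + FRIED_SHARED_LOADING * u
        df[name] = (rng.random(n) < expit(logit)).astype(int)
    sex = df["sex"].to_numpy()
    log_mu = np.where(sex == "female", GAIT_LOG_MEAN["female"], GAIT_LOG_MEAN["male"])
    df["gait_time"] = np.exp(log_mu + GAIT_SHARED_LOADING * u + rng.normal(0, GAIT_LOG_NOISE_SD, n))
    return df
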