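"""End-to-end orchestration of the two study designs:
simulate (or load) -> genotype QC -> frailty scoring -> MR -> report.

Each run produces a report bundle of plain delimited tables — genotype-lipid
associations, covariate balance, instrument diagnostics, and one causal
estimate per requested adjustment model — plus a human-readable summary.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import frailty, genetics, io, mr, simulate

log = logging.getLogger("lipidmr")

DESIGNS = ("longevity-case-control", "frailty-cross-sectional")
CONTROL_SETS = ("longevity-arm-controls", "combined-controls")
LIPIDS = ("triglyceride", "hdl_c", "ldl_c")


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    design: str = "longevity-case-control"
    input_path: str | None = None          # cohort file; simulated when absent
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    models: tuple = (1, 2, 3, 4)
    bootstrap_B: int = 1000
    seed: int = 0
    control_set: str = "longevity-arm-controls"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.control_set not in CONTROL_SETS:
            raise ConfigError(f"control_set must be one of {CONTROL_SETS}")
        self.models = tuple(int(m) for m in self.models)
        if not set(self.models) <= {1, 2, 3, 4}:
            raise ConfigError(f"model ids must be within {{1,2,3,4}}, got {self.models}")
        if 4 in self.models and self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be >= 1 when model 4 is requested")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def params(self) -> simulate.SimulationParams:
        base = (
            simulate.default_longevity_params(seed=self.seed)
            if self.design == "longevity-case-control"
            else simulate.default_ageing_params(seed=self.seed)
        )
        overrides = dict(self.simulation)
        overrides.setdefault("seed", self.seed)
        return dataclasses.replace(base, **overrides)


def _estimate_row(est: mr.CausalEstimate, outcome: str) -> dict:
    return {
        "outcome": outcome,
        "model": est.model_id,
        "method": est.method,
        "scale": est.scale,
        "point": est.point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p": est.p,
        "n": est.n,
        "n_dropped_replicates": est.n_dropped_replicates,
    }


def genotype_lipid_table(cohort: pd.DataFrame, lipids=LIPIDS) -> pd.DataFrame:
    """Per-genotype lipid summaries with dummy (TC/CC vs TT) and additive OLS
    effects — the published genotype-association table shape."""
    rows = []
    for lipid in lipids:
        if lipid not in cohort.columns:
            continue
        y = pd.to_numeric(cohort[lipid], errors="coerce")
        for scheme in ("dummy", "additive"):
            X = genetics.code_genotype(cohort["genotype"], scheme)
            mask = X.notna().all(axis=1) & y.notna()
            res = sm.OLS(y[mask].to_numpy(), sm.add_constant(X[mask].to_numpy())).fit()
            names = ["TC_vs_TT", "CC_vs_TT"] if scheme == "dummy" else ["per_C_allele"]
            for j, name in enumerate(names, start=1):
                rows.append(
                    {
                        "lipid": lipid,
                        "contrast": name,
                        "beta": float(res.params[j]),
                        "se": float(res.bse[j]),
                        "p": float(res.pvalues[j]),
                        "n": int(res.nobs),
                    }
                )
        for g, label in ((0, "TT"), (1, "TC"), (2, "CC")):
            vals = y[(cohort["genotype"] == g) & y.notna()]
            rows.append(
                {
                    "lipid": lipid,
                    "contrast": f"{label}_mean_sd",
                    "beta": float(vals.mean()) if len(vals) else np.nan,
                    "se": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "p": np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


BALANCE_COVARIATES = [
    "sex", "illiterate", "currently_married", "regular_smoker",
    "regular_drinker", "bmi", "sbp", "dbp",
]


def _load_or_simulate(config: AnalysisConfig) -> pd.DataFrame:
    if config.input_path:
        log.info("loading cohort from %s", config.input_path)
        return io.read_cohort(config.input_path)
    params = config.params()
    log.info("simulating %s cohort (seed=%d)", config.design, params.seed)
    if config.design == "longevity-case-control":
        cohort = simulate.generate_longevity_case_control(params)
        if config.control_set == "combined-controls":
            extra = simulate.generate_ageing_cohort(
                simulate.default_ageing_params(
                    seed=params.seed,
                    causal_logOR_longevity=params.causal_logOR_longevity,
                )
            )
            extra = extra.drop(columns=[c for c in extra.columns if c not in cohort.columns])
            extra["longevity"] = 0
            extra["arm"] = "ageing"
            cohort = pd.concat([cohort, extra], ignore_index=True)
            log.info("combined-controls sensitivity set: control n=%d", int((cohort["longevity"] == 0).sum()))
        return cohort
    return simulate.generate_ageing_cohort(params)


def run_longevity_analysis(config: AnalysisConfig) -> dict:
    """Case-control MR of triglycerides on longevity under the requested models."""
    if config.design != "longevity-case-control":
        raise ConfigError("config.design must be 'longevity-case-control'")
    cohort = _load_or_simulate(config)
    controls = cohort[cohort["longevity"] == 0]
    stage1_mask = cohort["longevity"] == 0  # stage 1 fitted in the comparison group

    qc = genetics.qc_report(controls)  # HWE belongs to the comparison group, never cases
    lipid_assoc = genotype_lipid_table(controls)
    balance = mr.confounder_balance(cohort, BALANCE_COVARIATES)
    s1 = mr.stage1_fit(controls)
    log.info("stage 1: beta=%.4f se=%.4f F=%.1f R2=%.4f n=%d", s1.beta, s1.se, s1.f_stat, s1.r2, s1.n)

    rows = []
    for m in sorted(config.models):
        covs = mr.MODEL_COVARIATES["longevity"][m]
        rows.append(_estimate_row(mr.reduced_form(cohort, "longevity", binary=True, covariates=covs, model_id=m), "longevity"))
        if m == 4:
            est = mr.bootstrap_mr(
                cohort, "longevity", binary=True, B=config.bootstrap_B,
                seed=config.seed, model_id=4, design="longevity", stage1_mask=stage1_mask,
            )
        else:
            _, est = mr.two_stage(cohort, "longevity", binary=True, model_id=m, design="longevity", stage1_cohort=controls)
        rows.append(_estimate_row(est, "longevity"))
        log.info("model %d: causal OR %.3f (%.3f, %.3f) n=%d dropped=%d", m, est.point, est.ci_low, est.ci_high, est.n, est.n_dropped_replicates)
        rows.append(_estimate_row(mr.observational_assoc(cohort, "longevity", binary=True, model_id=m, design="longevity"), "longevity"))
    estimates = pd.DataFrame(rows)

    stage1 = pd.DataFrame([dataclasses.asdict(s1) | {"weak_instrument": s1.weak_instrument}])
    return {"cohort": cohort, "qc": qc, "lipid_assoc": lipid_assoc, "balance": balance, "stage1": stage1, "estimates": estimates}


def run_frailty_analysis(config: AnalysisConfig) -> dict:
    """Cross-sectional MR of triglycerides on the frailty index (linear) and
    the Fried phenotype (logistic) in the ageing arm."""
    if config.design != "frailty-cross-sectional":
        raise ConfigError("config.design must be 'frailty-cross-sectional'")
    cohort = _load_or_simulate(config)
    scored = frailty.score_cohort(cohort)
    scored["frail"] = scored["phenotype"].map({"frail": 1.0, "non-frail": 0.0})
    log.info("scored %d subjects: mean FI=%.4f, frail fraction=%.4f",
             len(scored), scored["fi"].mean(), scored["frail"].mean())

    qc = genetics.qc_report(scored)
    lipid_assoc = genotype_lipid_table(scored)
    balance = mr.confounder_balance(scored, ["age"] + BALANCE_COVARIATES)
    s1 = mr.stage1_fit(scored)
    log.info("stage 1 (ageing arm): beta=%.4f F=%.1f R2=%.4f n=%d", s1.beta, s1.f_stat, s1.r2, s1.n)

    rows = []
    for m in sorted(config.models):
        covs = mr.MODEL_COVARIATES["frailty"][m]
        for outcome, binary in (("fi", False), ("frail", True)):
            rows.append(_estimate_row(mr.reduced_form(scored, outcome, binary=binary, covariates=covs, model_id=m), outcome))
            if m == 4:
                est = mr.bootstrap_mr(scored, outcome, binary=binary, B=config.bootstrap_B,
                                      seed=config.seed, model_id=4, design="frailty")
            else:
                _, est = mr.two_stage(scored, outcome, binary=binary, model_id=m, design="frailty")
            rows.append(_estimate_row(est, outcome))
            rows.append(_estimate_row(mr.observational_assoc(scored, outcome, binary=binary, model_id=m, design="frailty"), outcome))
    estimates = pd.DataFrame(rows)

    stage1 = pd.DataFrame([dataclasses.asdict(s1) | {"weak_instrument": s1.weak_instrument}])
    return {"cohort": scored, "qc": qc, "lipid_assoc": lipid_assoc, "balance": balance, "stage1": stage1, "estimates": estimates}


def run(config: AnalysisConfig) -> dict:
    if config.design == "longevity-case-control":
        return run_longevity_analysis(config)
    return run_frailty_analysis(config)


def write_report(bundle: dict, out_dir, seed: int | None = None) -> None:
    """Write every bundle table as CSV plus a human-readable summary.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        if name == "cohort":
            io.write_cohort(df, out / "cohort.csv")
        else:
            df.to_csv(out / f"{name}.csv", index=False, na_rep="NA")
    lines = []
    if seed is not None:
        lines.append(f"seed: {seed}")
    for name in ("qc", "stage1", "balance", "lipid_assoc", "estimates"):
        if name in bundle:
            lines.append(f"== {name} ==")
            lines.append(bundle[name].to_string(index=False))
            lines.append("")
    (out / "summary.txt").write_text("\n".join(lines))
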