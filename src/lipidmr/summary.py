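"""Reconstruction of regression and association quantities from grouped
per-genotype summary statistics.

Because the additive genotype takes only three values, count-weighted
regression of the per-genotype means on allele count reproduces the
individual-level OLS slope exactly; the per-genotype SDs supply the
within-group sum of squares needed for R^2 and the overall F. This is the
bridge from a published genotype-by-lipid table to testable stage-1 numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GenotypeCounts


class UndefinedSlopeError(ValueError):
    """Raised when fewer than two genotype groups are non-empty."""


@dataclass(frozen=True)
class GroupedLipidSummary:
    """Per-genotype (0, 1, 2 C alleles) count, mean and SD of one lipid, mmol/L."""

    n: tuple[int, int, int]
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n):
            raise ValueError("group counts must be non-negative")
        if any(s < 0 for s in self.sd):
            raise ValueError("group SDs must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.n))


@dataclass(frozen=True)
class GroupedOlsResult:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    n: int


def grouped_ols(summary: GroupedLipidSummary, within: str = "population") -> GroupedOlsResult:
    """Count-weighted simple regression of lipid level on allele count.

    slope = sum w_g (x_g - xbar)(ybar_g - ybar) / sum w_g (x_g - xbar)^2 with
    w_g = n_g, identical to the individual-level OLS slope. R^2 is the
    regression sum of squares over the total (between-group + within-group,
    the latter pooled from the SDs); F = (N-2) * R^2 / (1 - R^2).

    within='population' pools the within-group variance as sum n_g sd_g^2
    (exact when the SDs were computed with ddof=0); within='sample' uses
    sum (n_g - 1) sd_g^2 (exact for ddof=1 SDs). The two are indistinguishable
    at published-table sample sizes.
    """
    if within not in ("population", "sample"):
        raise ValueError("within must be 'population' or 'sample'")
    w = np.asarray(summary.n, dtype=float)
    if (w > 0).sum() < 2:
        raise UndefinedSlopeError("need at least two non-empty genotype groups")
    x = np.array([0.0, 1.0, 2.0])
    m = np.asarray(summary.mean, dtype=float)
    s = np.asarray(summary.sd, dtype=float)
    n_total = w.sum()
    xbar = (w * x).sum() / n_total
    ybar = (w * m).sum() / n_total
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (m - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_regression = slope * sxy
    ss_between = (w * (m - ybar) ** 2).sum()
    if within == "population":
        ss_within = (w * s**2).sum()
    else:
        ss_within = (np.clip(w - 1, 0, None) * s**2).sum()
    ss_total = ss_between + ss_within
    r2 = ss_regression / ss_total if ss_total > 0 else 0.0
    f_stat = (n_total - 2) * r2 / (1 - r2) if r2 < 1 else np.inf
    return GroupedOlsResult(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        f_stat=float(f_stat),
        n=int(n_total),
    )


def cohort_to_grouped_summary(
    cohort: pd.DataFrame,
    value_col: str = "triglyceride",
    genotype_col: str = "genotype",
    ddof: int = 0,
) -> GroupedLipidSummary:
    """Collapse an individual-level cohort to the per-genotype (n, mean, sd) shape.

    ddof=0 (population SDs) makes grouped_ols(within='population') reproduce
    the individual-level R^2 exactly; ddof=1 pairs with within='sample'.
    """
    df = cohort[[genotype_col, value_col]].dropna()
    n, mean, sd = [], [], []
    for g in (0, 1, 2):
        vals = df.loc[df[genotype_col] == g, value_col].to_numpy(dtype=float)
        n.append(len(vals))
        mean.append(float(vals.mean()) if len(vals) else 0.0)
        sd.append(float(vals.std(ddof=ddof)) if len(vals) > ddof else 0.0)
    return GroupedLipidSummary(n=tuple(n), mean=tuple(mean), sd=tuple(sd))


@dataclass(frozen=True)
class AllelicOrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # True when the Haldane-Anscombe 0.5 correction was applied


def allelic_or(case_counts: GenotypeCounts, control_counts: GenotypeCounts) -> AllelicOrResult:
    """Per-allele odds ratio from the 2x2 allele table (C vs T, cases vs controls).

    CI and p are Wald on the log-OR scale. A zero cell triggers the
    Haldane-Anscombe 0.5 correction (flagged in the result).
    """
    case_c = 2 * case_counts.n_CC + case_counts.n_TC
    case_t = 2 * case_counts.n_TT + case_counts.n_TC
    ctrl_c = 2 * control_counts.n_CC + control_counts.n_TC
    ctrl_t = 2 * control_counts.n_TT + control_counts.n_TC
    if (case_c + ctrl_c) == 0 or (case_t + ctrl_t) == 0:
        raise ValueError("both alleles must be observed in at least one group")
    cells = np.array([case_c, case_t, ctrl_c, ctrl_t], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt((1 / cells).sum())
    z = stats.norm.ppf(0.975)
    return AllelicOrResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p=float(2 * stats.norm.sf(abs(log_or) / se)),
        corrected=corrected,
    )


def read_grouped_summary(path) -> GroupedLipidSummary:
    """Read a per-genotype summary from a delimited file (genotype, n, mean, sd).

    The genotype column may hold allele counts 0/1/2 or TT/TC/CC strings.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    key = {"tt": 0, "tc": 1, "cc": 2, "0": 0, "1": 1, "2": 2}
    rows = {}
    for _, row in df.iterrows():
        g = key[str(row["genotype"]).strip().lower()]
        rows[g] = (int(row["n"]), float(row["mean"]), float(row["sd"]))
    n, mean, sd = [], [], []
    for g in (0, 1, 2):
        entry = rows.get(g, (0, 0.0, 0.0))
        n.append(entry[0])
        mean.append(entry[1])
        sd.append(entry[2])
    return GroupedLipidSummary(n=tuple(n), mean=tuple(mean), sd=tuple(sd))
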