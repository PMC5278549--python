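"""Frailty scoring: the 45-item cumulative-deficit frailty index (FI) and the
modified Fried frailty phenotype.

The FI is the mean of 45 health-deficit items each scored in [0, 1]; with
complete data it is the deficit sum divided by 45. The Fried phenotype counts
five criteria (unintentional weight loss, weakness, exhaustion, slowness, low
activity); three or more present classifies the subject as frail. Slowness is
defined from a timed up-and-go test as gait speed below the sex-specific 20th
percentile, i.e. completion time strictly above the sex-specific 80th
percentile of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

N_DEFICITS = 45
DEFICIT_COLUMNS = [f"d{i:02d}" for i in range(1, N_DEFICITS + 1)]
# self-report criteria; slowness is derived from gait_time and is the fifth
FRIED_BOOL_COLUMNS = ["weight_loss", "exhaustion", "low_activity", "weakness"]

SLOW_PERCENTILE = 0.20  # slow = below the 20th sex-specific gait-speed percentile
MIN_NONMISSING_FRACTION = 0.80  # rescaling policy needs >= 36 of 45 items observed
FRAIL_CRITERIA = 3  # frail iff >= 3 of the 5 Fried criteria are met


class DeficitValidationError(ValueError):
    """Raised for deficit values outside [0, 1] or malformed codebooks."""


class StratumMissingError(ValueError):
    """Raised when a requested sex stratum has no gait-time data."""


@dataclass(frozen=True)
class DeficitItem:
    """One health-deficit item: raw levels mapped to severities in [0, 1].

    Dichotomous items map {0, 1} -> {0.0, 1.0}; polychotomous items map k
    ordered levels to equally spaced grades by default (0, 1/(k-1), ..., 1).
    """

    name: str
    kind: str  # 'dichotomous' | 'polychotomous'
    mapping: dict

    def __post_init__(self) -> None:
        if self.kind not in ("dichotomous", "polychotomous"):
            raise DeficitValidationError(f"unknown deficit kind {self.kind!r}")
        values = list(self.mapping.values())
        if not values or any(not (0.0 <= v <= 1.0) for v in values):
            raise DeficitValidationError(f"item {self.name!r}: mapped values must lie in [0, 1]")
        if min(values) != 0.0 or max(values) != 1.0:
            raise DeficitValidationError(
                f"item {self.name!r}: mapping must include 0 and its maximum level must map to 1"
            )

    @classmethod
    def equally_spaced(cls, name: str, n_levels: int) -> "DeficitItem":
        if n_levels < 2:
            raise DeficitValidationError("need at least 2 levels")
        kind = "dichotomous" if n_levels == 2 else "polychotomous"
        mapping = {lvl: lvl / (n_levels - 1) for lvl in range(n_levels)}
        return cls(name=name, kind=kind, mapping=mapping)


@dataclass(frozen=True)
class DeficitCodebook:
    """The 45 item definitions used to turn raw questionnaire levels into deficits."""

    items: tuple

    def __post_init__(self) -> None:
        if len(self.items) != N_DEFICITS:
            raise DeficitValidationError(f"a codebook must define exactly {N_DEFICITS} items")

    @classmethod
    def from_yaml(cls, path) -> "DeficitCodebook":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        items = tuple(
            DeficitItem(name=d["name"], kind=d["kind"], mapping={int(k): float(v) for k, v in d["mapping"].items()})
            for d in raw["items"]
        )
        return cls(items=items)

    def to_yaml(self, path) -> None:
        payload = {
            "items": [
                {"name": it.name, "kind": it.kind, "mapping": {int(k): float(v) for k, v in it.mapping.items()}}
                for it in self.items
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def equally_spaced_default(cls, n_polychotomous: int = 15, max_levels: int = 5) -> "DeficitCodebook":
        """A generic 45-item codebook: dichotomous items plus `n_polychotomous`
        graded items with equally spaced severities (3..max_levels levels)."""
        items = []
        for i in range(N_DEFICITS):
            if i < N_DEFICITS - n_polychotomous:
                items.append(DeficitItem.equally_spaced(DEFICIT_COLUMNS[i], 2))
            else:
                levels = 3 + (i % (max_levels - 2))
                items.append(DeficitItem.equally_spaced(DEFICIT_COLUMNS[i], levels))
        return cls(items=tuple(items))

    def apply(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Map raw level columns (named as the items) to deficit columns d01..d45."""
        out = {}
        for col, item in zip(DEFICIT_COLUMNS, self.items):
            src = raw[item.name]
            out[col] = src.map(lambda v: np.nan if pd.isna(v) else item.mapping[int(v)])
        return pd.DataFrame(out, index=raw.index)


@dataclass(frozen=True)
class FrailtyResult:
    """Per-subject frailty scores."""

    fi: float  # NaN when not computable
    n_deficits_used: int
    phenotype: str  # 'frail' | 'non-frail' | 'missing'
    n_criteria_met: int  # observed-true criteria (lower bound under missingness)


def frailty_index(deficits, policy: str = "rescale") -> tuple[float, int]:
    """FI for one subject from a 45-vector of deficits in [0, 1] (NaN = missing).

    policy='rescale' divides the deficit sum by the number of non-missing
    items, provided at least 80% (36/45) are observed, else FI is missing.
    policy='strict' always divides by 45 and returns missing FI if any item is
    missing. Returns (fi, n_deficits_used).
    """
    v = np.asarray(deficits, dtype=float)
    if v.shape != (N_DEFICITS,):
        raise DeficitValidationError(f"expected a length-{N_DEFICITS} deficit vector, got shape {v.shape}")
    observed = ~np.isnan(v)
    if observed.any() and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
        raise DeficitValidationError("deficit values must lie in [0, 1]")
    n_obs = int(observed.sum())
    if policy == "strict":
        if n_obs < N_DEFICITS:
            return np.nan, n_obs
        return float(v.sum() / N_DEFICITS), N_DEFICITS
    if policy == "rescale":
        if n_obs < int(np.ceil(MIN_NONMISSING_FRACTION * N_DEFICITS)):
            return np.nan, n_obs
        return float(np.nansum(v) / n_obs), n_obs
    raise ValueError(f"unknown missing-data policy {policy!r}")


def slowness_threshold(gait_times: pd.Series, sex: pd.Series) -> dict:
    """Sex-specific gait-time cutoffs for slowness.

    Returns {sex: cutoff} where the cutoff is the empirical 80th percentile of
    completion times in that stratum (linear interpolation). A subject is slow
    when their time is STRICTLY above the cutoff, which is the literal reading
    of "below the 20th percentile in gait speed"; ties at the cutoff are
    non-slow. A stratum with no non-missing times raises StratumMissingError.
    """
    times = pd.Series(gait_times).astype(float)
    sexes = pd.Series(sex)
    cutoffs = {}
    for s in sexes.dropna().unique():
        vals = times[(sexes == s) & times.notna()].to_numpy()
        if len(vals) == 0:
            raise StratumMissingError(f"no gait times observed for sex stratum {s!r}")
        cutoffs[s] = float(np.quantile(vals, 1.0 - SLOW_PERCENTILE))
    return cutoffs


def flag_slow(gait_times: pd.Series, sex: pd.Series, cutoffs: dict | None = None) -> pd.Series:
    """Boolean slowness flag per subject (NaN gait time -> NaN flag)."""
    if cutoffs is None:
        cutoffs = slowness_threshold(gait_times, sex)
    times = pd.Series(gait_times).astype(float)
    out = pd.Series(np.nan, index=times.index, dtype=object)
    for s, cut in cutoffs.items():
        mask = (pd.Series(sex) == s) & times.notna()
        out[mask] = times[mask] > cut
    return out


def fried_phenotype(
    weight_loss, exhaustion, low_activity, weakness, slow
) -> tuple[str, int]:
    """Classify one subject from the five Fried criteria (each True/False/None).

    Frail iff >= 3 criteria are met. With missing components the call is made
    only when decidable: >= 3 observed-true -> frail; >= 3 observed-false ->
    non-frail; otherwise missing. Returns (phenotype, n_observed_true).
    """
    comps = [weight_loss, exhaustion, low_activity, weakness, slow]
    n_true = sum(1 for c in comps if c is not None and not pd.isna(c) and bool(c))
    n_false = sum(1 for c in comps if c is not None and not pd.isna(c) and not bool(c))
    if n_true >= FRAIL_CRITERIA:
        return "frail", n_true
    if n_false >= 5 - FRAIL_CRITERIA + 1:  # >= 3 false: can no longer reach 3 true
        return "non-frail", n_true
    return "missing", n_true


def score_cohort(
    cohort: pd.DataFrame,
    policy: str = "rescale",
    cutoffs: dict | None = None,
) -> pd.DataFrame:
    """Append fi, n_deficits_used, phenotype, n_criteria_met columns to a cohort.

    Requires deficit columns d01..d45 and the Fried component columns
    (weight_loss, exhaustion, low_activity, weakness, gait_time) plus sex.
    Slowness cutoffs are computed within the cohort unless supplied. This is
    the vectorised counterpart of the per-subject `frailty_index` /
    `fried_phenotype` functions and agrees with them row by row.
    """
    out = cohort.copy()
    deficits = cohort[DEFICIT_COLUMNS].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(deficits, initial=0.0) < 0 or np.nanmax(deficits, initial=0.0) > 1:
            raise DeficitValidationError("deficit values must lie in [0, 1]")
    observed = ~np.isnan(deficits)
    n_obs = observed.sum(axis=1)
    if policy == "strict":
        fi = np.where(n_obs == N_DEFICITS, np.nansum(deficits, axis=1) / N_DEFICITS, np.nan)
        n_used = np.where(n_obs == N_DEFICITS, N_DEFICITS, n_obs)
    elif policy == "rescale":
        min_items = int(np.ceil(MIN_NONMISSING_FRACTION * N_DEFICITS))
        with np.errstate(invalid="ignore", divide="ignore"):
            fi = np.where(n_obs >= min_items, np.nansum(deficits, axis=1) / np.maximum(n_obs, 1), np.nan)
        n_used = n_obs
    else:
        raise ValueError(f"unknown missing-data policy {policy!r}")
    out["fi"] = fi
    out["n_deficits_used"] = n_used.astype(int)

    slow = flag_slow(cohort["gait_time"], cohort["sex"], cutoffs=cutoffs)
    comps = np.column_stack(
        [pd.to_numeric(cohort[c], errors="coerce").to_numpy(dtype=float) for c in FRIED_BOOL_COLUMNS]
        + [pd.Series([np.nan if pd.isna(v) else float(bool(v)) for v in slow]).to_numpy()]
    )
    n_true = np.nansum(comps == 1.0, axis=1).astype(int)
    n_false = np.nansum(comps == 0.0, axis=1).astype(int)
    phenotype = np.where(
        n_true >= FRAIL_CRITERIA, "frail", np.where(n_false >= 5 - FRAIL_CRITERIA + 1, "non-frail", "missing")
    )
    out["phenotype"] = phenotype
    out["n_criteria_met"] = n_true
    return out
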