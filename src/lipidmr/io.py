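"""Cohort file I/O: comma-separated text, one row per subject, header row,
"NA" for missing. Deficit items are columns d01..d45; Fried components are
named columns (weight_loss, exhaustion, low_activity, weakness, gait_time)."""

from __future__ import annotations

import pandas as pd

# canonical leading column order; deficit/Fried/score columns follow when present
BASE_COLUMNS = [
    "id", "arm", "age", "sex",
    "illiterate", "currently_married", "regular_smoker", "regular_drinker",
    "bmi", "sbp", "dbp",
    "genotype", "triglyceride", "hdl_c", "ldl_c",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    lead = [c for c in BASE_COLUMNS if c in cohort.columns]
    rest = [c for c in cohort.columns if c not in lead]
    cohort[lead + rest].to_csv(path, index=False, na_rep="NA")


def read_cohort(path) -> pd.DataFrame:
    # genotype may arrive as allele counts or TT/TC/CC strings; downstream
    # coders accept either form, so no coercion happens here
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)
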