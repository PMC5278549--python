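import numpy as np
import pandas as pd
import pytest

import lipidmr as lm

# Table-shaped reference inputs used across tests: the comparison-group
# genotype counts and the per-genotype triglyceride summaries.
COMPARISON_COUNTS = lm.GenotypeCounts(1150, 953, 191)
TG_GROUPED = lm.GroupedLipidSummary(
    n=(1150, 953, 191), mean=(1.29, 1.46, 2.09), sd=(0.82, 0.86, 1.70)
)


@pytest.fixture(scope="session")
def case_control_cohort() -> pd.DataFrame:
    """One default-size case-control cohort (438 cases / 2294 controls)."""
    return lm.generate_longevity_case_control(lm.default_longevity_params(seed=101))


@pytest.fixture(scope="session")
def scored_ageing_cohort() -> pd.DataFrame:
    """Default ageing arm (n=1750) with FI and Fried phenotype scored."""
    cohort = lm.generate_ageing_cohort(lm.default_ageing_params(seed=202))
    scored = lm.score_cohort(cohort)
    scored["frail"] = scored["phenotype"].map({"frail": 1.0, "non-frail": 0.0})
    return scored


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_small_cohort(rng: np.random.Generator, n: int = 200) -> pd.DataFrame:
    """A minimal genotype/exposure frame for regression identities."""
    g = rng.binomial(2, rng.uniform(0.1, 0.5), size=n).astype(float)
    y = 1.0 + rng.normal(0, 1, n) + rng.uniform(-0.5, 0.5) * g
    return pd.DataFrame({"genotype": g, "triglyceride": y})
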