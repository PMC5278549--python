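import numpy as np
import pandas as pd
import pytest

import lipidmr as lm
from lipidmr.mr import (
    MODEL_COVARIATES,
    ConvergenceError,
    NoEstimateError,
    SingularDesignError,
)

from conftest import random_small_cohort


def _cohort(g, y, **extra):
    df = pd.DataFrame({"genotype": np.asarray(g, dtype=float), "triglyceride": np.asarray(y, dtype=float)})
    for k, v in extra.items():
        df[k] = v
    return df


class TestStage1:
    def test_exact_line(self):
        s1 = lm.stage1_fit(_cohort([0, 1, 2], [1.0, 2.0, 3.0]))
        assert s1.beta == pytest.approx(1.0, abs=1e-10)
        assert s1.intercept == pytest.approx(1.0, abs=1e-10)
        assert s1.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_exposure(self):
        s1 = lm.stage1_fit(_cohort([0, 1, 2, 1], [1.5, 1.5, 1.5, 1.5]))
        assert s1.beta == 0.0 and s1.r2 == 0.0 and s1.f_stat == 0.0

    def test_no_genotype_variation(self):
        with pytest.raises(SingularDesignError):
            lm.stage1_fit(_cohort([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0]))

    def test_f_equals_t_squared_single_predictor(self, rng):
        cohort = random_small_cohort(rng, n=300)
        s1 = lm.stage1_fit(cohort)
        assert s1.f_stat == pytest.approx((s1.beta / s1.se) ** 2, rel=1e-8)
        assert 0 <= s1.r2 <= 1

    def test_weak_instrument_gate(self):
        strong = lm.Stage1Result(beta=0.3, se=0.03, intercept=1.3, f_stat=95.3, r2=0.04, n=2294)
        weak = lm.Stage1Result(beta=0.05, se=0.05, intercept=1.3, f_stat=1.0, r2=0.001, n=500)
        assert not strong.weak_instrument
        assert weak.weak_instrument

    def test_complete_case_n(self, rng):
        cohort = random_small_cohort(rng, n=100)
        cohort.loc[:9, "triglyceride"] = np.nan
        assert lm.stage1_fit(cohort).n == 90


class TestPredictExposure:
    def test_table_arithmetic(self):
        s1 = lm.Stage1Result(beta=0.301, se=0.031, intercept=1.29, f_stat=95.3, r2=0.04, n=2294)
        pred = lm.predict_exposure(s1, _cohort([0, 1, 2], [1, 1, 1]))
        assert pred.tolist() == pytest.approx([1.29, 1.591, 1.892])

    def test_zero_beta_constant_prediction(self):
        s1 = lm.Stage1Result(beta=0.0, se=0.1, intercept=1.4, f_stat=0.0, r2=0.0, n=100)
        pred = lm.predict_exposure(s1, _cohort([0, 1, 2], [1, 1, 1]))
        assert (pred == 1.4).all()

    def test_missing_genotype_missing_prediction(self):
        s1 = lm.Stage1Result(beta=0.3, se=0.03, intercept=1.3, f_stat=90, r2=0.04, n=100)
        df = _cohort([0.0, 1.0], [1, 1])
        df.loc[2] = [np.nan, 1.0]
        pred = lm.predict_exposure(s1, df)
        assert np.isnan(pred.iloc[2])
        # and the subject drops out of the stage-2 complete-case sample
        df["y"] = [0.1, 0.2, 0.3]
        est = lm.stage2_continuous(df, pred, "y")
        assert est.n == 2


class TestWaldRatio:
    def test_published_identity(self):
        """OR 0.86 per allele over 0.301 mmol/L per allele gives the causal
        OR 0.61 per mmol/L reported for the unadjusted model."""
        est = lm.wald_ratio(np.log(0.86), 0.301, binary=True)
        assert round(est.point, 2) == 0.61

    def test_null_outcome_effect(self):
        assert lm.wald_ratio(np.log(1.0), 0.45, binary=True).point == pytest.approx(1.0)

    def test_linear_ratio(self):
        est = lm.wald_ratio(0.003, 0.375, binary=False)
        assert est.point == pytest.approx(0.008)

    def test_zero_stage1_rejected(self):
        with pytest.raises(ZeroDivisionError):
            lm.wald_ratio(0.1, 0.0)

    def test_delta_method_ci_brackets_point(self):
        est = lm.wald_ratio(np.log(0.86), 0.301, binary=True, se_gy=0.085, se_stage1=0.031)
        assert est.ci_low < est.point < est.ci_high
        assert 0 < est.p < 1


class TestTwoStage:
    def test_equals_wald_ratio_for_continuous_outcome(self, rng):
        """Single-instrument identity: with no covariates and a continuous
        outcome, the two-stage slope equals reduced-form / stage-1 exactly."""
        for _ in range(5):
            cohort = random_small_cohort(rng, n=250)
            cohort["fi"] = 0.1 + 0.02 * cohort["triglyceride"] + rng.normal(0, 0.05, 250)
            s1 = lm.stage1_fit(cohort)
            _, two_stage_est = lm.two_stage(cohort, "fi", binary=False, model_id=1, design="frailty")
            rf = lm.reduced_form(cohort, "fi", binary=False)
            assert two_stage_est.point == pytest.approx(rf.point / s1.beta, abs=1e-8)

    def test_outcome_equal_to_prediction_recovers_unit_slope(self, rng):
        cohort = random_small_cohort(rng, n=200)
        s1 = lm.stage1_fit(cohort)
        pred = lm.predict_exposure(s1, cohort)
        est = lm.stage2_continuous(cohort, pred, pd.Series(pred, index=cohort.index))
        assert est.point == pytest.approx(1.0, abs=1e-10)
        assert est.ci_high - est.ci_low < 1e-8

    def test_constant_prediction_rejected(self, rng):
        cohort = random_small_cohort(rng, n=100)
        cohort["y"] = rng.random(100)
        with pytest.raises(NoEstimateError):
            lm.stage2_continuous(cohort, pd.Series(1.4, index=cohort.index), "y")

    def test_single_outcome_class_rejected(self, rng):
        cohort = random_small_cohort(rng, n=100)
        cohort["y"] = 1.0
        with pytest.raises(NoEstimateError):
            lm.stage2_binary(cohort, cohort["triglyceride"], "y")

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 80)
        cohort = pd.DataFrame({"x": x, "y": (x > 0).astype(float)})
        with pytest.raises(ConvergenceError):
            lm.stage2_binary(cohort, cohort["x"], "y")

    def test_ci_on_reporting_scale(self, case_control_cohort):
        controls = case_control_cohort[case_control_cohort["longevity"] == 0]
        _, est = lm.two_stage(
            case_control_cohort, "longevity", binary=True, model_id=1,
            design="longevity", stage1_cohort=controls,
        )
        assert est.ci_low <= est.point <= est.ci_high
        assert est.scale == "log-odds per mmol/L"
        assert est.n <= len(case_control_cohort)

    def test_complete_case_n_varies_with_model(self, case_control_cohort):
        cohort = case_control_cohort.copy()
        cohort.loc[cohort.index[:100], "bmi"] = np.nan
        controls = cohort[cohort["longevity"] == 0]
        _, m1 = lm.two_stage(cohort, "longevity", binary=True, model_id=1, design="longevity", stage1_cohort=controls)
        _, m3 = lm.two_stage(cohort, "longevity", binary=True, model_id=3, design="longevity", stage1_cohort=controls)
        assert m3.n == m1.n - 100

    def test_adjustment_ladder_as_published(self):
        assert MODEL_COVARIATES["longevity"][1] == []
        assert MODEL_COVARIATES["longevity"][2] == ["sex"]
        assert set(MODEL_COVARIATES["longevity"][3]) == {
            "sex", "illiterate", "currently_married", "regular_smoker",
            "regular_drinker", "bmi", "sbp", "dbp",
        }
        assert MODEL_COVARIATES["frailty"][2] == ["age", "sex"]
        assert MODEL_COVARIATES["frailty"][4] == ["age", "sex"]  # model 4 bootstraps model 2


class TestBootstrap:
    def test_percentile_ci_brackets_point(self, rng):
        cohort = random_small_cohort(rng, n=400)
        cohort["fi"] = 0.1 + 0.03 * cohort["triglyceride"] + rng.normal(0, 0.05, 400)
        est = lm.bootstrap_mr(cohort, "fi", binary=False, B=200, seed=7, design="frailty", covariates=[])
        assert est.ci_low <= est.point <= est.ci_high
        assert est.method == "bootstrap-two-stage"

    def test_single_replicate_degenerate_ci(self, rng):
        cohort = random_small_cohort(rng, n=200)
        cohort["fi"] = 0.1 + 0.02 * cohort["triglyceride"] + rng.normal(0, 0.05, 200)
        est = lm.bootstrap_mr(cohort, "fi", binary=False, B=1, seed=3, design="frailty", covariates=[])
        assert est.ci_low == pytest.approx(est.ci_high)

    def test_reproducible_for_fixed_seed(self, rng):
        cohort = random_small_cohort(rng, n=200)
        cohort["fi"] = 0.1 + 0.02 * cohort["triglyceride"] + rng.normal(0, 0.05, 200)
        a = lm.bootstrap_mr(cohort, "fi", binary=False, B=50, seed=11, design="frailty", covariates=[])
        b = lm.bootstrap_mr(cohort, "fi", binary=False, B=50, seed=11, design="frailty", covariates=[])
        assert a == b

    def test_invalid_b_rejected(self, rng):
        cohort = random_small_cohort(rng, n=50)
        cohort["fi"] = rng.random(50)
        with pytest.raises(ValueError):
            lm.bootstrap_mr(cohort, "fi", binary=False, B=0, seed=1)


class TestObservationalContrast:
    def test_confounded_observational_vs_null_mr(self, rng):
        """With a confounder driving both exposure and outcome and no causal
        effect, the observational slope is biased away from zero while the MR
        estimate stays centred on the null — the design's core rationale."""
        n = 3000
        u = rng.normal(0, 1, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        tg = 1.3 + 0.3 * g + 0.8 * u + rng.normal(0, 0.5, n)
        y = 0.1 + 0.05 * u + rng.normal(0, 0.05, n)  # outcome depends on U only
        cohort = pd.DataFrame({"genotype": g, "triglyceride": tg, "fi": y})
        obs = lm.observational_assoc(cohort, "fi", binary=False, covariates=[])
        _, mr_est = lm.two_stage(cohort, "fi", binary=False, model_id=1, design="frailty")
        assert obs.point > 0.02 and obs.p < 1e-6
        assert mr_est.ci_low < 0 < mr_est.ci_high

    def test_independent_exposure_gives_null_or(self, rng):
        n = 2000
        cohort = pd.DataFrame(
            {
                "genotype": rng.binomial(2, 0.3, n).astype(float),
                "triglyceride": rng.normal(1.4, 0.9, n),
                "y": rng.binomial(1, 0.3, n).astype(float),
            }
        )
        est = lm.observational_assoc(cohort, "y", binary=True, covariates=[])
        assert est.ci_low < 1.0 < est.ci_high


class TestConfounderBalance:
    def test_covariate_equal_to_genotype_detected(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        cohort = pd.DataFrame({"genotype": g, "mirror": g, "noise": rng.normal(0, 1, 500)})
        table = lm.confounder_balance(cohort, ["mirror", "noise"])
        assert table.loc[table.covariate == "mirror", "p"].iloc[0] < 1e-10
        assert table.loc[table.covariate == "noise", "p"].iloc[0] > 0.001

    def test_identical_group_distributions_zero_statistic(self):
        g = np.repeat([0.0, 1.0, 2.0], 3)
        vals = np.tile([1.0, 2.0, 3.0], 3)
        cohort = pd.DataFrame({"genotype": g, "cont": vals})
        table = lm.confounder_balance(cohort, ["cont"])
        assert table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_entirely_missing_covariate_flagged(self, rng):
        cohort = pd.DataFrame({"genotype": rng.binomial(2, 0.3, 50).astype(float), "gone": np.nan})
        table = lm.confounder_balance(cohort, ["gone"])
        assert table["test"].iloc[0] == "missing"

    def test_tests_match_variable_kinds(self, case_control_cohort):
        table = lm.confounder_balance(case_control_cohort, ["sex", "bmi", "regular_smoker"])
        kinds = dict(zip(table.covariate, table.test))
        assert kinds["sex"] == "chi-squared"
        assert kinds["regular_smoker"] == "chi-squared"
        assert kinds["bmi"] == "kruskal-wallis"
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
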