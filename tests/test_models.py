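"""Association models: OLS engine, trend test, marginal means, interactions."""

import numpy as np
import pandas as pd
import pytest

from portfoliodiet.models import (ModelSpec, RankDeficiencyError, attach_scores,
                                  back_transform, component_regression,
                                  default_covariates, fit_linear,
                                  interaction_test, marginal_means, trend_test)


def _toy_cohort(n=120, seed=0, noise=0.0, slope=-0.02):
    """Small frame with pds, tertile columns and numeric covariates."""
    rng = np.random.default_rng(seed)
    pds = rng.integers(6, 31, n).astype(float)
    age = rng.normal(23, 3, n)
    z = rng.normal(0, 1, n)
    y = 2.3 + slope * pds + 0.01 * age + 0.5 * z + noise * rng.normal(0, 1, n)
    tert = pd.qcut(pds, 3, labels=["T1", "T2", "T3"])
    medians = {t: np.median(pds[tert == t]) for t in ("T1", "T2", "T3")}
    return pd.DataFrame({
        "pds": pds, "age": age, "z": z, "y": y,
        "tertile": tert.astype(str),
        "tertile_median_pds": pd.Series(tert.astype(str)).map(medians),
    })


class TestOlsEngine:
    def test_noiseless_fit_is_exact(self):
        df = _toy_cohort(noise=0.0)
        res = fit_linear(ModelSpec(outcome="y", covariates=("age", "z")), df)
        assert res.beta_per_point == pytest.approx(-0.02, abs=1e-10)
        assert res.n_used == len(df)

    def test_matches_normal_equations_oracle(self):
        df = _toy_cohort(n=20, seed=3, noise=0.3)
        res = fit_linear(ModelSpec(outcome="y", covariates=("age", "z")), df)
        X = np.column_stack([np.ones(len(df)), df["pds"], df["age"], df["z"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert res.beta_per_point == pytest.approx(beta[1], rel=1e-8)

    def test_per_8_rescaling_is_exact(self):
        df = _toy_cohort(noise=0.4, seed=5)
        res = fit_linear(ModelSpec(outcome="y", covariates=("age",)), df)
        assert res.beta_per_8 == 8 * res.beta_per_point
        assert res.ci95_per_8[0] == pytest.approx(8 * res.ci95[0])
        assert res.ci95_per_8[1] == pytest.approx(8 * res.ci95[1])

    def test_rank_deficiency_names_aliased_column(self):
        df = _toy_cohort()
        df["z"] = 1.0  # constant, aliased with the intercept
        with pytest.raises(RankDeficiencyError, match="z"):
            fit_linear(ModelSpec(outcome="y", covariates=("age", "z")), df)

    def test_irrelevant_covariate_barely_moves_estimate(self):
        df = _toy_cohort(n=400, seed=11, noise=0.5)
        rng = np.random.default_rng(99)
        df["junk"] = rng.normal(0, 1, len(df))
        base = fit_linear(ModelSpec(outcome="y", covariates=("age", "z")), df)
        plus = fit_linear(ModelSpec(outcome="y", covariates=("age", "z", "junk")), df)
        se = (base.ci95[1] - base.ci95[0]) / (2 * 1.96)
        assert abs(plus.beta_per_point - base.beta_per_point) < 3 * se


class TestTransforms:
    def test_log_fit_reports_proportional_difference(self):
        rng = np.random.default_rng(2)
        df = _toy_cohort(n=500, seed=2)
        df["y"] = np.exp(0.5 - 0.01 * df["pds"] + 0.05 * rng.normal(0, 1, 500))
        res = fit_linear(ModelSpec(outcome="y", transform="log"), df)
        expected = (np.exp(res.beta_per_point) - 1) * df["y"].mean()
        assert res.reported_beta == pytest.approx(expected)
        assert res.beta_per_point == pytest.approx(-0.01, abs=2e-3)

    @pytest.mark.parametrize("beta,mean,expected", [
        (0.0, 1.0, 0.0),
        (-0.01, 1.0, np.expm1(-0.01)),   # -0.00995: proportional difference
    ])
    def test_back_transform_log_closed_form(self, beta, mean, expected):
        got, _ = back_transform(beta, "log", mean)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_back_transform_identity_and_sqrt(self):
        assert back_transform(0.3, "none", 5.0)[0] == 0.3
        assert back_transform(0.1, "sqrt", 4.0)[0] == pytest.approx(2 * 2.0 * 0.1)

    def test_log_requires_positive_outcome(self):
        df = _toy_cohort()
        df.loc[0, "y"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_linear(ModelSpec(outcome="y", transform="log"), df)


class TestMarginalMeans:
    def test_no_covariates_equal_raw_tertile_means(self):
        df = _toy_cohort(n=300, seed=8, noise=0.5)
        means, n = marginal_means(df, "y")
        raw = df.groupby("tertile")["y"].mean()
        for t in ("T1", "T2", "T3"):
            assert means[t][0] == pytest.approx(raw[t], abs=1e-10)
        assert n == len(df)

    def test_binary_covariate_hand_average(self):
        # marginal mean at tertile t = prediction averaged over the observed
        # covariate distribution = b_t + b_z * mean(z)
        df = _toy_cohort(n=200, seed=9, noise=0.4)
        df["z"] = (df["z"] > 0).astype(float)
        means, _ = marginal_means(df, "y", covariates=("z",))
        X = np.column_stack([np.ones(len(df)),
                             (df["tertile"] == "T2").astype(float),
                             (df["tertile"] == "T3").astype(float),
                             df["z"]])
        b = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        zbar = df["z"].mean()
        hand = {"T1": b[0] + b[3] * zbar,
                "T2": b[0] + b[1] + b[3] * zbar,
                "T3": b[0] + b[2] + b[3] * zbar}
        for t, expected in hand.items():
            assert means[t][0] == pytest.approx(expected, abs=1e-8)

    def test_means_track_negative_slope(self, scored_cohort):
        means, _ = marginal_means(scored_cohort, "ldl_nih")
        assert means["T1"][0] > means["T3"][0]


class TestTrendTest:
    def test_noiseless_trend_is_certain(self):
        df = _toy_cohort(n=150, seed=4, noise=0.0)
        df["y"] = 3.0 - 0.1 * df["tertile_median_pds"]
        assert trend_test(df, "y") < 1e-10

    def test_degenerate_tertiles_rejected(self):
        df = _toy_cohort()
        df["tertile"] = "T1"
        df["tertile_median_pds"] = 18.0
        with pytest.raises(ValueError, match="one tertile"):
            trend_test(df, "y")

    def test_explicit_medians_accepted(self):
        df = _toy_cohort(n=200, seed=6, noise=0.3)
        p = trend_test(df, "y", tertile_medians={"T1": 13, "T2": 18, "T3": 23})
        assert 0.0 <= p <= 1.0

    def test_permutation_calibration_quick(self):
        # under a permuted exposure the trend p-value should be uniform;
        # check the rejection rate at alpha=0.05 over 400 permutations
        df = _toy_cohort(n=250, seed=13, noise=1.0, slope=0.0)
        rng = np.random.default_rng(20)
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(len(df))
            shuffled = df.copy()
            cols = ["tertile", "tertile_median_pds", "pds"]
            shuffled[cols] = df[cols].to_numpy()[perm]
            if trend_test(shuffled, "y", covariates=("age",)) < 0.05:
                rejections += 1
        rate = rejections / n_perm
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_perm)


class TestInteractions:
    def test_null_interaction_not_significant(self):
        rng = np.random.default_rng(17)
        df = _toy_cohort(n=600, seed=17, noise=0.0)
        df["sex"] = np.where(rng.random(600) < 0.5, "female", "male")
        df["y"] = 2.3 - 0.02 * df["pds"] + 0.3 * rng.normal(0, 1, 600)
        p, strata = interaction_test(df, "y", "sex")
        assert p > 0.05  # seeded: identical true slopes in both strata
        assert set(strata) == {"female", "male"}

    def test_planted_sex_specific_slopes_recovered(self):
        rng = np.random.default_rng(23)
        n = 6000
        pds = rng.integers(6, 31, n).astype(float)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        slope = np.where(sex == "male", -0.023, -0.006)
        y = 2.5 + slope * pds + 0.1 * rng.normal(0, 1, n)
        df = pd.DataFrame({"pds": pds, "sex": sex, "y": y})
        p, strata = interaction_test(df, "y", "sex")
        assert p < 0.001
        assert strata["male"][0] == pytest.approx(-0.023, abs=0.002)
        assert strata["female"][0] == pytest.approx(-0.006, abs=0.002)

    def test_single_stratum_rejected(self):
        df = _toy_cohort()
        df["sex"] = "female"
        with pytest.raises(ValueError, match="single stratum"):
            interaction_test(df, "y", "sex")


class TestComponentModels:
    def test_phytosterol_serving_conversion(self):
        # 25 mg = 1 serving: a noiseless per-mg slope of b becomes 25*b per serving
        rng = np.random.default_rng(31)
        n = 80
        mg = rng.lognormal(np.log(250), 0.5, n)
        df = pd.DataFrame({"phytosterols": mg, "y": 4.0 - 0.004 * mg})
        res = component_regression(df, "phytosterols", "y")
        assert res.beta_per_point == pytest.approx(-0.004 * 25, abs=1e-10)

    def test_zero_variance_component_is_rank_deficient(self):
        df = pd.DataFrame({"nuts": np.ones(50),
                           "y": np.random.default_rng(1).normal(0, 1, 50)})
        with pytest.raises(RankDeficiencyError):
            component_regression(df, "nuts", "y")

    def test_planted_nut_effect_recovered(self):
        rng = np.random.default_rng(37)
        n = 3000
        nuts = rng.lognormal(np.log(0.4), 1.0, n)
        y = 2.4 - 0.049 * nuts + 0.3 * rng.normal(0, 1, n)
        df = pd.DataFrame({"nuts": nuts, "y": y})
        res = component_regression(df, "nuts", "y")
        se = (res.ci95[1] - res.ci95[0]) / (2 * 1.96)
        assert res.beta_per_point == pytest.approx(-0.049, abs=2.5 * se)


class TestSpecValidation:
    def test_bmi_banned_for_adiposity_outcomes(self):
        with pytest.raises(ValueError, match="adiposity"):
            ModelSpec(outcome="fmi", covariates=("bmi", "age"))
        assert "bmi" not in default_covariates("bmi")
        assert "bmi" in default_covariates("ldl_nih")

    def test_component_exposure_needs_component(self):
        with pytest.raises(ValueError, match="component"):
            ModelSpec(outcome="y", exposure="component_servings")

    def test_full_covariate_fit_on_default_cohort(self, scored_cohort):
        res = fit_linear(
            ModelSpec(outcome="ldl_nih", covariates=default_covariates("ldl_nih")),
            scored_cohort)
        assert res.n_used > 1400
        se = (res.ci95[1] - res.ci95[0]) / (2 * 1.96)
        assert abs(res.beta_per_point - (-0.009)) < 4 * se  # single-seed check

    def test_attach_scores_columns(self, scored_cohort):
        assert {"pds", "tertile", "tertile_median_pds"} <= set(scored_cohort.columns)
        assert scored_cohort["pds"].between(6, 30).all()
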