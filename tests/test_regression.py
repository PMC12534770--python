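"""Moderation, simple slopes, nested logistic models, and VIF screening."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from climaffect.regression import (
    ModelError,
    RegressionFit,
    fit_logistic_nested,
    fit_moderation,
    probe_interaction,
    vif_screen,
)
from climaffect.simulate import StructuralTruth, SyntheticConfig

from conftest import build_analysis


@pytest.fixture(scope="module")
def moderated_analysis():
    """Generator with a known summer x temperature interaction of -0.1."""
    truth = StructuralTruth(summer_temp_interaction=-0.1)
    cfg = SyntheticConfig(
        n_regions=3,
        baseline_years=3,
        posts_per_region_day_mean=20.0,
        exposure="temp_change",
        structural=truth,
        seed=14,
    )
    analysis, _, _ = build_analysis(cfg)
    return analysis


@pytest.fixture(scope="module")
def null_interaction_analysis():
    cfg = SyntheticConfig(
        n_regions=3,
        baseline_years=3,
        posts_per_region_day_mean=20.0,
        exposure="temp_change",
        seed=15,
    )
    analysis, _, _ = build_analysis(cfg)
    return analysis


def _interaction_term(fit, level="summer"):
    (term,) = [
        t for t in fit.terms if level in t and ":" in t
    ]
    return term


class TestModeration:
    def test_null_interaction_recovered(self, null_interaction_analysis):
        fit = fit_moderation(
            null_interaction_analysis, "ewb", "temp_change", "season"
        )
        term = _interaction_term(fit)
        row = fit.table.loc[term]
        assert abs(row["estimate"]) < 3 * row["se"]

    def test_known_interaction_recovered(self, moderated_analysis):
        fit = fit_moderation(moderated_analysis, "ewb", "temp_change", "season")
        term = _interaction_term(fit)
        row = fit.table.loc[term]
        assert row["estimate"] == pytest.approx(-0.1, abs=3 * row["se"])
        assert fit.reference_levels["season"] == "spring"

    def test_single_level_moderator_reduces_to_exposure_model(
        self, null_interaction_analysis
    ):
        summer_only = null_interaction_analysis[
            null_interaction_analysis["season"] == "summer"
        ]
        fit = fit_moderation(summer_only, "ewb", "temp_change", "season")
        assert fit.terms == ["Intercept", "temp_change"]

    def test_treatment_coding_reproduces_cell_means(self):
        # saturated binary-exposure x season model: predicted value in each
        # (x=0, season) cell must equal that cell's sample mean
        rng = np.random.default_rng(23)
        n = 400
        data = pd.DataFrame(
            {
                "x": rng.integers(0, 2, n).astype(float),
                "season": rng.choice(["spring", "summer", "autumn", "winter"], n),
                "ewb": rng.normal(size=n),
            }
        )
        fit = fit_moderation(data, "ewb", "x", "season")
        intercept = fit.coef("Intercept")
        for season in ("spring", "summer", "autumn", "winter"):
            cell = data[(data["season"] == season) & (data["x"] == 0)]
            coef = 0.0 if season == "spring" else fit.coef(
                _season_main_term(fit, season)
            )
            assert intercept + coef == pytest.approx(cell["ewb"].mean(), abs=1e-8)


def _season_main_term(fit, level):
    (term,) = [t for t in fit.terms if level in t and ":" not in t]
    return term


class TestProbeInteraction:
    @pytest.fixture()
    def crafted_fit(self):
        terms = ["Intercept", "x", "m", "x:m"]
        table = pd.DataFrame(
            {
                "estimate": [0.0, -0.06, 0.0, -0.07],
                "se": [0.01, 0.02, 0.01, 0.03],
            },
            index=terms,
        )
        cov = pd.DataFrame(np.zeros((4, 4)), index=terms, columns=terms)
        cov.loc["x", "x"] = 0.02**2
        cov.loc["x:m", "x:m"] = 0.03**2
        return RegressionFit(
            family="linear", terms=terms, table=table, n=100, cov_params=cov
        )

    def test_plug_in_slopes(self, crafted_fit):
        slopes = probe_interaction(crafted_fit, "x", "x:m", [0.0, 1.0])
        assert slopes.loc[0, "slope"] == pytest.approx(-0.06)
        assert slopes.loc[1, "slope"] == pytest.approx(-0.13)

    def test_se_at_zero_probe_equals_main_effect_se(self, crafted_fit):
        slopes = probe_interaction(crafted_fit, "x", "x:m", [0.0])
        assert slopes.loc[0, "se"] == pytest.approx(0.02)

    def test_zero_interaction_gives_identical_slopes(self, crafted_fit):
        crafted_fit.table.loc["x:m", "estimate"] = 0.0
        slopes = probe_interaction(crafted_fit, "x", "x:m", [-1.0, 1.0])
        assert slopes["slope"].nunique() == 1

    def test_unknown_term_rejected(self, crafted_fit):
        with pytest.raises(ModelError, match="not in fitted model"):
            probe_interaction(crafted_fit, "x", "x:z", [0.0])


class TestNestedLogistic:
    def test_single_binary_predictor_matches_cross_product_ratio(self):
        # exposed: 30 events / 70 non-events; unexposed: 50 / 50 -> OR 0.4286
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(50), np.zeros(50)]
        df = pd.DataFrame({"x": x, "pro_env": y})
        (fit,) = fit_logistic_nested(df, "pro_env", [["x"]])
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(
            30 * 50 / (70 * 50), abs=1e-6
        )

    def test_independent_outcome_has_null_pseudo_r2(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=5_000),
                "pro_env": rng.integers(0, 2, 5_000),
            }
        )
        (fit,) = fit_logistic_nested(df, "pro_env", [["x"]])
        assert 0 <= fit.pseudo_r2 < 0.01

    def test_fully_mediated_weather_effect_attenuates(self):
        # weather reaches pro_env only through well-being: adding ewb must
        # pull the weather odds ratio toward 1. The intercept centres the
        # linear predictor at the mean well-being level (~12.9) so the
        # prevalence is informative rather than degenerate.
        truth = StructuralTruth(logit_coefs=(-5.16, 0.0, 0.4, 0.0, 0.0, 0.0))
        cfg = SyntheticConfig(
            n_regions=3,
            baseline_years=2,
            posts_per_region_day_mean=25.0,
            structural=truth,
            seed=17,
        )
        analysis, _, _ = build_analysis(cfg)
        fits = fit_logistic_nested(
            analysis, "pro_env", [["extreme_hot"], ["ewb"]]
        )
        crude = np.log(fits[0].table.loc["extreme_hot", "odds_ratio"])
        adjusted = np.log(fits[1].table.loc["extreme_hot", "odds_ratio"])
        assert abs(adjusted) < abs(crude)
        assert crude < 0  # hot days lower well-being, hence pro-env odds

    def test_log_likelihood_monotone_in_blocks(self, null_interaction_analysis):
        df = null_interaction_analysis.copy()
        for col in ("population_density_high", "sensitivity_high"):
            df[col] = df[col].astype(float)
        fits = fit_logistic_nested(
            df,
            "pro_env",
            [["extreme_hot"], ["ewb"], ["affiliation", "analytic", "somatosensory"]],
        )
        lls = [f.llf for f in fits]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0] * 10, "pro_env": [0, 1, 2] * 10})
        with pytest.raises(ModelError, match="binary"):
            fit_logistic_nested(df, "pro_env", [["x"]])


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        design = pd.DataFrame(
            {
                "x1": np.tile([1.0, -1.0], n // 2),
                "x2": np.repeat([1.0, -1.0], n // 2),
            }
        )
        table, removed = vif_screen(design)
        np.testing.assert_allclose(table["vif"], 1.0, atol=1e-12)
        assert removed == []

    def test_exact_correlation_0p8_gives_278(self):
        rng = np.random.default_rng(18)
        v = rng.normal(size=200)
        w = rng.normal(size=200)
        v = (v - v.mean()) / v.std()
        w = w - w.mean()
        w -= v * (v @ w) / (v @ v)  # make w empirically orthogonal to v
        w /= w.std()
        design = pd.DataFrame({"x1": v, "x2": 0.8 * v + 0.6 * w})
        table, removed = vif_screen(design)
        assert removed == []
        np.testing.assert_allclose(table["vif"], 1.0 / (1.0 - 0.64), atol=1e-6)

    def test_near_duplicate_predictor_removed(self):
        rng = np.random.default_rng(19)
        x1 = rng.normal(size=100)
        design = pd.DataFrame(
            {"x1": x1, "x2": x1 + rng.normal(0, 1e-4, 100), "x3": rng.normal(size=100)}
        )
        table, removed = vif_screen(design)
        assert len(removed) == 1 and removed[0] in ("x1", "x2")
        assert (table["vif"] <= 5).all()

    def test_perfect_collinearity_reported_infinite_and_removed(self):
        x1 = np.arange(50.0)
        design = pd.DataFrame(
            {"x1": x1, "x2": 2.0 * x1, "x3": np.random.default_rng(20).normal(size=50)}
        )
        _, removed = vif_screen(design)
        assert removed and removed[0] in ("x1", "x2")

    def test_constant_column_rejected(self):
        design = pd.DataFrame({"x1": np.ones(10), "x2": np.arange(10.0)})
        with pytest.raises(ModelError, match="constant column"):
            vif_screen(design)
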