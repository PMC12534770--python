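"""Path estimation, implied moments, fit indices, and BCa machinery."""

import numpy as np
import pandas as pd
import pytest

from climaffect.mediation import (
    EstimationError,
    PathEstimates,
    PathModelSpec,
    bca_interval,
    bias_correction,
    bootstrap_effects,
    fit_indices,
    fit_paths,
    implied_covariance,
)

SPEC = PathModelSpec(n_boot=200, seed=9)


def _structural_sample(n, a, b, c_prime, seed, p_exposed=0.1):
    """Independent data construction (plain numpy, no package generator)."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_exposed).astype(float)
    M = np.asarray(a) * x[:, None] + rng.normal(size=(n, 3))
    y = c_prime * x + M @ np.asarray(b) + rng.normal(size=n)
    return pd.DataFrame(
        {
            "extreme_hot": x,
            "affiliation": M[:, 0],
            "analytic": M[:, 1],
            "somatosensory": M[:, 2],
            "ewb": y,
        }
    )


class TestFitPaths:
    def test_binary_exposure_a_is_group_mean_difference(self):
        df = _structural_sample(500, (-0.5, -0.3, 0.2), (0.9, 0.3, 0.1), -0.2, 1)
        est = fit_paths(df, SPEC)
        grp = df.groupby("extreme_hot")["affiliation"].mean()
        assert est.a[0] == pytest.approx(grp[1.0] - grp[0.0], abs=1e-12)

    def test_identity_path_limit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2_000)
        df = pd.DataFrame(
            {
                "extreme_hot": x,
                "affiliation": rng.normal(size=x.size),
                "analytic": rng.normal(size=x.size),
                "somatosensory": rng.normal(size=x.size),
                "ewb": x,
            }
        )
        est = fit_paths(df, SPEC)
        assert est.c_prime == pytest.approx(1.0, abs=0.01)
        assert np.abs(est.indirect).max() < 0.01

    def test_effect_decomposition_is_exact(self):
        df = _structural_sample(300, (-0.5, -0.3, 0.2), (0.9, 0.3, 0.1), -0.2, 3)
        est = fit_paths(df, SPEC)
        assert est.total == pytest.approx(
            est.c_prime + float(np.sum(est.a * est.b)), abs=1e-14
        )

    def test_product_of_coefficients_equals_difference_of_coefficients(self):
        # with all mediators in one linear equation, the slope of y on x alone
        # equals c' + sum a_k b_k in sample, to machine precision
        df = _structural_sample(400, (-0.5, -0.3, 0.2), (0.9, 0.3, 0.1), -0.2, 4)
        est = fit_paths(df, SPEC)
        x = df["extreme_hot"].to_numpy()
        y = df["ewb"].to_numpy()
        slope = np.cov(x, y, bias=True)[0, 1] / x.var()
        assert est.total == pytest.approx(slope, abs=1e-12)

    def test_constant_exposure_rejected(self):
        df = _structural_sample(100, (0, 0, 0), (0, 0, 0), 0.0, 5)
        df["extreme_hot"] = 1.0
        with pytest.raises(EstimationError, match="constant exposure"):
            fit_paths(df, SPEC)

    def test_recovery_error_shrinks_with_sample_size(self):
        truth = dict(a=(-0.5, -0.3, 0.2), b=(0.9, 0.3, 0.1), c_prime=-0.2)
        errs = {}
        for n in (500, 50_000):
            est = fit_paths(_structural_sample(n, **truth, seed=6), SPEC)
            errs[n] = max(
                np.abs(est.a - truth["a"]).max(),
                np.abs(est.b - truth["b"]).max(),
                abs(est.c_prime - truth["c_prime"]),
            )
        assert errs[50_000] < errs[500]
        assert errs[50_000] < 0.05


class TestImpliedCovariance:
    def test_zero_coefficients_give_block_diagonal(self):
        est = PathEstimates(
            a=np.zeros(3),
            b=np.zeros(3),
            c_prime=0.0,
            mediator_intercepts=np.zeros(3),
            y_intercept=0.0,
            psi=np.diag([1.0, 2.0, 3.0]),
            theta_y=4.0,
            var_x=0.25,
            n=100,
        )
        S = implied_covariance(est)
        np.testing.assert_allclose(S, np.diag([0.25, 1.0, 2.0, 3.0, 4.0]))

    def test_just_identified_entries_reproduce_sample_moments(self):
        # every entry not involving the constrained (m2, m3) residual
        # covariance must equal the sample moment exactly
        df = _structural_sample(600, (-0.5, -0.3, 0.2), (0.9, 0.3, 0.1), -0.2, 7)
        est = fit_paths(df, SPEC)
        cols = ["extreme_hot", "affiliation", "analytic", "somatosensory", "ewb"]
        S_sample = np.cov(df[cols].to_numpy().T, bias=True)
        S_model = implied_covariance(est)
        free = np.ones((5, 5), bool)
        for i, j in [(2, 3), (2, 4), (3, 4), (4, 4)]:
            free[i, j] = free[j, i] = False
        np.testing.assert_allclose(S_model[free], S_sample[free], atol=1e-10)
        # and the constrained block converges only in expectation
        assert np.abs(S_model - S_sample).max() < 0.5


class TestFitIndices:
    def test_perfect_fit(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        idx = fit_indices(S, S, n=1000, q_free=2)
        assert idx["chi_square"] == pytest.approx(0.0, abs=1e-9)
        assert idx["cfi"] == 1.0
        assert idx["rmsea"] == pytest.approx(0.0, abs=1e-9)

    def test_three_mediator_specification_has_one_degree_of_freedom(self):
        df = _structural_sample(300, (-0.5, -0.3, 0.2), (0.9, 0.3, 0.1), -0.2, 8)
        est = fit_paths(df, SPEC)
        cols = ["extreme_hot", "affiliation", "analytic", "somatosensory", "ewb"]
        S = np.cov(df[cols].to_numpy().T, bias=True)
        idx = fit_indices(S, implied_covariance(est), est.n)
        assert idx["df"] == 1

    def test_independence_baseline_calibrated_on_uncorrelated_data(self):
        rng = np.random.default_rng(10)
        S = np.cov(rng.normal(size=(5, 2000)), bias=True)
        idx = fit_indices(S, S, n=2000, q_free=14)
        # baseline chi-square ~ chi2(df=10): mean 10, sd sqrt(20)
        assert abs(idx["chi_square_baseline"] - 10) < 3 * np.sqrt(20)

    def test_non_positive_definite_named(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        good = np.eye(2)
        with pytest.raises(EstimationError, match="sample covariance"):
            fit_indices(S, good, n=100, q_free=2)


class TestBCa:
    def test_reduces_to_percentile_interval_without_corrections(self):
        rng = np.random.default_rng(13)
        ts = rng.normal(size=999)
        lo, hi = bca_interval(ts, z0=0.0, ahat=0.0, level=0.95)
        qlo, qhi = np.quantile(ts, [0.025, 0.975], method="linear")
        assert lo == qlo and hi == qhi

    def test_toy_replicates_interpolated_endpoints(self):
        ts = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        lo, hi = bca_interval(ts, z0=0.0, ahat=0.0, level=0.95)
        assert lo == pytest.approx(1.1)
        assert hi == pytest.approx(4.9)

    def test_bias_correction_proportion_is_clamped(self):
        from scipy.special import ndtri

        ts = np.arange(5.0)
        assert bias_correction(ts, -10.0) == pytest.approx(ndtri(1 / 6))
        assert bias_correction(ts, 10.0) == pytest.approx(ndtri(5 / 6))


class TestBootstrapEffects:
    def test_seeded_bootstrap_is_reproducible(self, medium_analysis):
        spec = PathModelSpec(n_boot=100, seed=21)
        f1 = bootstrap_effects(medium_analysis, spec)
        f2 = bootstrap_effects(medium_analysis, spec)
        pd.testing.assert_frame_equal(f1.to_frame(), f2.to_frame())

    def test_different_seeds_move_intervals_slightly(self, medium_analysis):
        f1 = bootstrap_effects(medium_analysis, PathModelSpec(n_boot=100, seed=1))
        f2 = bootstrap_effects(medium_analysis, PathModelSpec(n_boot=100, seed=2))
        d = abs(f1.effects["total"].ci_low - f2.effects["total"].ci_low)
        assert 0 < d < 0.1
        assert f1.effects["total"].estimate == f2.effects["total"].estimate

    def test_interval_brackets_point_estimate(self, medium_analysis):
        fit = bootstrap_effects(medium_analysis, PathModelSpec(n_boot=200, seed=3))
        for name, eff in fit.effects.items():
            assert eff.ci_low <= eff.estimate <= eff.ci_high, name

    def test_nonzero_effect_has_small_p(self, medium_analysis):
        fit = bootstrap_effects(medium_analysis, PathModelSpec(n_boot=200, seed=4))
        assert fit.effects["total"].p < 0.01
        assert fit.effects["indirect_1"].p < 0.01

    def test_overly_rare_exposure_aborts(self):
        rng = np.random.default_rng(30)
        n = 24
        df = pd.DataFrame(
            {
                "extreme_hot": np.r_[np.ones(1), np.zeros(n - 1)],
                "affiliation": rng.normal(size=n),
                "analytic": rng.normal(size=n),
                "somatosensory": rng.normal(size=n),
                "ewb": rng.normal(size=n),
            }
        )
        with pytest.raises(EstimationError, match="constant exposure|10%"):
            bootstrap_effects(df, PathModelSpec(n_boot=100, seed=5))
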