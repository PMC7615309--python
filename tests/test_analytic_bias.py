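"""Closed-form maximum-bias and SE results, and the logit/probit conversion."""

import math

import numpy as np
import pytest

from collidermi import (
    SummaryStats,
    alpha_obs_limit,
    bias_bound,
    conditional_regression,
    implied_moments,
    logor_from_probit,
    max_bias_covform,
    max_bias_exposure_alpha1,
    max_bias_outcome,
    odds_ratio_from_probit,
    probit_from_logor,
    relative_precision,
    se_profile,
    selected_moments,
)
from collidermi.analytic_bias import FormulaDomainError

from conftest import random_fig1_model


class TestMaxBiasOutcome:
    def test_all_unit_coefficients(self, fig1):
        assert max_bias_outcome(fig1) == pytest.approx(0.2)

    @pytest.mark.parametrize("edge", [("R", "X"), ("R", "U"), ("W", "U"), ("Y", "Z"), ("W", "Z")])
    def test_zero_factor_law(self, fig1, edge):
        """Any single zero direct effect kills the bias exactly."""
        assert max_bias_outcome(fig1.with_coefficients({edge: 0.0})) == 0.0

    def test_sign_follows_coefficient_product(self, fig1):
        assert max_bias_outcome(fig1.with_coefficients({("R", "X"): -1.0})) == pytest.approx(-0.2)

    def test_sign_rule_random_models(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            model = random_fig1_model(rng)
            product = (
                model.coefficient("R", "X")
                * model.coefficient("R", "U")
                * model.coefficient("W", "U")
                * model.coefficient("Y", "Z")
                * model.coefficient("W", "Z")
            )
            value = max_bias_outcome(model)
            assert math.copysign(1, value) == math.copysign(1, product) or value == product == 0

    def test_invariant_to_exposure_coefficient(self, fig1):
        values = {
            max_bias_outcome(fig1.with_coefficients({("Y", "X"): b})) for b in (-2.0, 0.0, 2.0)
        }
        assert len(values) == 1

    def test_wrong_scenario_rejected(self, fig4):
        with pytest.raises(FormulaDomainError):
            max_bias_outcome(fig4)


class TestBiasBound:
    def test_fig1_bound_is_conditional_coefficient_gap(self, fig1):
        lower, upper = bias_bound(fig1)
        assert lower == 0.0
        assert upper == pytest.approx(0.2, abs=1e-12)  # |1.2 - 1.0|

    def test_no_unmeasured_path_no_bias(self, fig1):
        lower, upper = bias_bound(fig1.with_coefficients({("W", "U"): 0.0}))
        assert (lower, upper) == (0.0, pytest.approx(0.0, abs=1e-12))

    def test_dual_route_equivalence_random_models(self):
        """|product formula| == |beta_YX|W,R - beta_YX| from Gaussian
        conditioning, across random Fig-1-shaped models."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            model = random_fig1_model(rng)
            _, bound = bias_bound(model)
            assert abs(max_bias_outcome(model)) == pytest.approx(bound, abs=1e-10)


class TestCovarianceForm:
    def test_cohort_published_inputs(self):
        """The printed summary statistics reproduce the published plug-in
        value 0.008 to 3 decimal places."""
        stats = SummaryStats.from_mapping(
            {"var_x": 0.228, "var_w": 0.286, "cov_yw": 0.171, "or_x_r": 2.31, "or_w_r": 1.15}
        )
        assert round(max_bias_covform(stats), 3) == 0.008

    def test_zero_collider_logor_gives_zero(self):
        stats = SummaryStats(var_x=0.25, var_w=0.3, cov_yw=0.2, logor_x_r=0.8, logor_w_r=0.0)
        assert max_bias_covform(stats) == 0.0

    def test_equivalence_with_effect_size_formula(self, fig1):
        """Standardizing R and rewriting the all-1s model in covariance form
        recovers (1/3)/(5/3) = 0.2."""
        stats = SummaryStats.from_path_model(fig1)
        assert max_bias_covform(stats) == pytest.approx(0.2, abs=1e-12)

    def test_equivalence_random_models(self):
        rng = np.random.default_rng(17)
        count = 0
        for _ in range(80):
            model = random_fig1_model(rng)
            stats = SummaryStats.from_path_model(model)
            try:
                cov_route = max_bias_covform(stats)
            except FormulaDomainError:
                continue
            count += 1
            assert cov_route == pytest.approx(max_bias_outcome(model), abs=1e-8)
        assert count >= 50

    def test_invalid_regime_rejected(self):
        stats = SummaryStats(var_x=0.01, var_w=0.01, cov_yw=0.2, logor_x_r=50.0, logor_w_r=50.0)
        with pytest.raises(FormulaDomainError):
            max_bias_covform(stats)


class TestExposureCase:
    def test_all_unit_coefficients(self, fig4):
        assert max_bias_exposure_alpha1(fig4) == pytest.approx(-1 / 104)

    def test_no_collider_missingness_path(self, fig4):
        assert max_bias_exposure_alpha1(fig4.with_coefficients({("W", "U"): 0.0})) == pytest.approx(0.0)

    def test_no_exposure_predictor_path(self, fig4):
        assert max_bias_exposure_alpha1(fig4.with_coefficients({("X", "Z"): 0.0})) == pytest.approx(
            0.0, abs=1e-12
        )


class TestSEProfile:
    def test_fig1_endpoints(self, fig1):
        rep = se_profile(fig1, 1000)
        assert rep.se_mi_at_0 == pytest.approx(math.sqrt(5 / 3000), abs=5e-5)
        assert rep.se_cra_at_0 == pytest.approx(math.sqrt(2 / 1000), abs=5e-5)
        assert rep.se_mi_limit == pytest.approx(math.sqrt(1.6 / (1000 * 0.625)), abs=5e-5)
        assert rep.se_cra_limit == pytest.approx(math.sqrt(2 / (1000 * 2 / 3)), abs=5e-5)

    def test_uncorrelated_collider_collapses_to_cra(self, fig1):
        model = fig1.with_coefficients({("Y", "Z"): 0.0})  # Cov(Y, W) = 0
        rep = se_profile(model, 1000)
        assert rep.se_mi_at_0 == pytest.approx(rep.se_cra_at_0)

    def test_small_n_rejected(self, fig1):
        with pytest.raises(ValueError):
            se_profile(fig1, 1)

    def test_cra_se_grows_with_missingness_random_models(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            rep = se_profile(random_fig1_model(rng), 500)
            assert rep.se_cra_limit >= rep.se_cra_at_0 - 1e-12


class TestRelativePrecision:
    def test_equal_se_gives_zero(self):
        assert relative_precision(0.3, 0.3) == 0.0

    def test_half_variance_gives_fifty(self):
        assert relative_precision(math.sqrt(0.5), 1.0) == pytest.approx(50.0)

    def test_fig1_limit_value(self, fig1):
        rep = se_profile(fig1, 1000)
        assert relative_precision(rep.se_mi_limit, rep.se_cra_limit) == pytest.approx(14.67, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_precision(0.0, 1.0)


class TestLogitProbit:
    @pytest.mark.parametrize(
        "probit, printed_or",
        [(0.0, 1.00), (0.25, 1.50), (0.5, 2.30), (0.75, 3.50), (1.0, 5.30)],
    )
    def test_published_conversion_table(self, probit, printed_or):
        """Probit coefficients correspond to the published approximate odds
        ratios (printed at roughly two significant figures)."""
        assert round(odds_ratio_from_probit(probit), 1) == pytest.approx(printed_or, abs=0.051)

    def test_or_to_probit(self):
        assert probit_from_logor(math.log(2.31)) == pytest.approx(0.502, abs=5e-4)

    def test_round_trip_identity(self):
        for logor in (-1.3, 0.0, 0.42, 2.0):
            assert logor_from_probit(probit_from_logor(logor)) == pytest.approx(logor)


class TestSelectedMoments:
    def test_no_missingness_is_identity(self, fig1, fig1_joint):
        sel = selected_moments(fig1, 0.0)
        np.testing.assert_allclose(sel.cov, fig1_joint.cov)

    def test_selection_shrinks_r_variance_only_along_r(self, fig1):
        sel = selected_moments(fig1, 0.5)
        joint = implied_moments(fig1)
        assert sel.var("R") < joint.var("R")
        # Z has no association with R, so selection leaves it untouched
        assert sel.var("Z") == pytest.approx(1.0)
        assert sel.mean_of("Z") == pytest.approx(0.0)

    def test_alpha_obs_limit_interpolates_bias_bound(self, fig1):
        """The exact complete-records coefficient runs from the unbiased value
        at pi0 = 0 to the maximum-bias value as pi0 -> 1."""
        at0 = alpha_obs_limit(fig1, 0.0).coefficient("X")
        assert at0 == pytest.approx(1.0)
        biases = [alpha_obs_limit(fig1, p).coefficient("X") - 1.0 for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(b2 > b1 for b1, b2 in zip(biases, biases[1:]))  # monotone growth
        assert biases[-1] < 0.2  # below the pi0 -> 1 bound
        # approach to the 0.2 bound is logarithmically slow in 1 - pi0
        near_one = alpha_obs_limit(fig1, 1.0 - 1e-15).coefficient("X") - 1.0
        assert 0.185 < near_one < 0.2

    def test_alpha_obs_limit_matches_large_sample_ols(self, fig1):
        """Gaussian-selection algebra agrees with brute-force OLS on a large
        selected sample."""
        from collidermi.experiments import replicate_estimates

        reps = 40
        seeds = np.random.SeedSequence(31).spawn(reps)
        est = replicate_estimates(fig1, 0.5, 20_000, reps, 2, seeds, run_mi=False)
        exact = alpha_obs_limit(fig1, 0.5).coefficient("X")
        mc_se = est["mi"].std(ddof=1) / math.sqrt(reps)
        assert abs(est["mi"].mean() - exact) < 4 * mc_se
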