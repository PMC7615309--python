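"""OLS, proper normal-linear imputation, and Rubin's-rules pooling."""

import math

import numpy as np
import pandas as pd
import pytest

from collidermi import (
    MissingnessSpec,
    StudyDataset,
    cra_estimate,
    impose_missingness,
    impute_normal,
    mi_analyze,
    ols_fit,
    pool_rubin,
    simulate_complete,
)


class TestOLSFit:
    def test_exact_recovery_on_noiseless_data(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "z": z, "y": 2.0 + 1.5 * x - 0.5 * z})
        fit = ols_fit(StudyDataset(df=df), "y", ["x", "z"])
        assert fit.estimate("const") == pytest.approx(2.0, abs=1e-10)
        assert fit.estimate("x") == pytest.approx(1.5, abs=1e-10)
        assert fit.estimate("z") == pytest.approx(-0.5, abs=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_recovers_structural_slope(self, fig1):
        data = simulate_complete(fig1, 100_000, seed=1)
        fit = ols_fit(data, "Y", ["X"])
        assert abs(fit.estimate("X") - 1.0) < 4 * fit.se("X")

    def test_conditioning_on_r_shifts_slope(self, fig1):
        """Regressing on the latent R reproduces the 1.2 conditional slope."""
        data = simulate_complete(fig1, 100_000, seed=2)
        fit = ols_fit(data, "Y", ["X", "W", "R"])
        assert abs(fit.estimate("X") - 1.2) < 4 * fit.se("X")

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.0, 3.0, 4.0]})
        df["x2"] = df["x"]
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(StudyDataset(df=df), "y", ["x", "x2"])

    def test_insufficient_rows_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ols_fit(StudyDataset(df=df), "y", ["x"])


class TestImputeNormal:
    def test_nothing_to_impute_is_an_error(self, fig1):
        data = simulate_complete(fig1, 100, seed=3)
        with pytest.raises(ValueError, match="no missing"):
            impute_normal(data, "Y", ["X"], m=5, seed=0)

    def test_missing_predictor_rejected(self, fig1):
        data = simulate_complete(fig1, 200, seed=3)
        data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.3))
        with pytest.raises(ValueError, match="missing entries"):
            impute_normal(data, "Y", ["Y"], m=5, seed=0)

    def test_same_seed_identical_imputations(self, fig1):
        data = simulate_complete(fig1, 500, seed=3)
        data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.4))
        a = impute_normal(data, "Y", ["X", "W"], m=3, seed=11)
        b = impute_normal(data, "Y", ["X", "W"], m=3, seed=11)
        for da, db in zip(a, b):
            assert da.equals(db)

    def test_observed_entries_untouched_and_m_copies(self, fig1):
        data = simulate_complete(fig1, 500, seed=4)
        data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.4))
        completed = impute_normal(data, "Y", ["X", "W"], m=4, seed=0)
        assert len(completed) == 4
        obs = data.df["Y"].notna()
        for dfj in completed:
            assert dfj["Y"].notna().all()
            np.testing.assert_array_equal(dfj.loc[obs, "Y"], data.df.loc[obs, "Y"])

    def test_m_below_two_rejected(self, fig1):
        data = simulate_complete(fig1, 100, seed=3)
        data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.3))
        with pytest.raises(ValueError):
            impute_normal(data, "Y", ["X"], m=1, seed=0)


class TestImputeBinary:
    @pytest.fixture()
    def binary_masked(self, fig1):
        from collidermi import dichotomize

        data = simulate_complete(fig1, 3000, seed=17)
        data = dichotomize(data, "Y", prevalence=0.5)
        return impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.4))

    def test_imputed_values_are_binary_and_observed_untouched(self, binary_masked):
        from collidermi import impute_binary

        completed = impute_binary(binary_masked, "Y", ["X", "W"], m=3, seed=1)
        obs = binary_masked.df["Y"].notna()
        for dfj in completed:
            assert set(np.unique(dfj["Y"])) <= {0.0, 1.0}
            np.testing.assert_array_equal(dfj.loc[obs, "Y"], binary_masked.df.loc[obs, "Y"])

    def test_reproducible_and_requires_missing(self, binary_masked, fig1):
        from collidermi import dichotomize, impute_binary

        a = impute_binary(binary_masked, "Y", ["X", "W"], m=3, seed=5)
        b = impute_binary(binary_masked, "Y", ["X", "W"], m=3, seed=5)
        for da, db in zip(a, b):
            assert da.equals(db)
        complete = dichotomize(simulate_complete(fig1, 500, seed=1), "Y", prevalence=0.5)
        with pytest.raises(ValueError, match="no missing"):
            impute_binary(complete, "Y", ["X"], m=3, seed=0)


class TestPoolRubin:
    def test_hand_worked_two_imputations(self):
        res = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert res.pooled_estimate == 2.0
        assert res.within_var == 1.0
        assert res.between_var == 2.0
        assert res.total_var == 4.0
        assert res.se == 2.0

    def test_identical_estimates_no_between_variance(self):
        res = pool_rubin([1.5, 1.5, 1.5], [0.2, 0.2, 0.2])
        assert res.between_var == 0.0
        assert res.total_var == res.within_var
        assert math.isinf(res.dof)

    def test_rubin_identity_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m = int(rng.integers(2, 40))
            est = rng.normal(size=m)
            var = rng.uniform(0.1, 2.0, size=m)
            res = pool_rubin(est, var)
            assert res.total_var == pytest.approx(
                res.within_var + (1 + 1 / m) * res.between_var, rel=1e-12
            )
            assert res.se == pytest.approx(math.sqrt(res.total_var), rel=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            pool_rubin([1.0], [1.0])


@pytest.fixture(scope="module")
def masked_fig1(fig1):
    data = simulate_complete(fig1, 2000, seed=21)
    return impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.5))


class TestMIAnalyze:
    def test_pooled_tracks_complete_records_coefficient(self, masked_fig1):
        """With many imputations the pooled estimate sits on top of the
        complete-records imputation-model coefficient."""
        res = mi_analyze(masked_fig1, "Y", ("X",), "Y", ("X", "W"), m=400, seed=5)
        assert res.pooled_estimate == pytest.approx(res.diagnostics["alpha_obs"], abs=0.01)

    def test_exposure_only_imputation_matches_cra(self, fig1):
        """Imputing from the exposure alone recovers nothing beyond complete
        records: the two estimators agree within Monte-Carlo error, pairwise."""
        diffs = []
        for seed in range(40):
            data = simulate_complete(fig1, 2000, seed=100 + seed)
            data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.5))
            res = mi_analyze(data, "Y", ("X",), "Y", ("X",), m=60, seed=seed)
            cra = cra_estimate(data, "Y", ("X",))
            diffs.append(res.pooled_estimate - cra.estimate("X"))
        assert abs(np.mean(diffs)) < 4 * np.std(diffs, ddof=1) / math.sqrt(len(diffs))

    def test_same_seed_reproducible(self, masked_fig1):
        a = mi_analyze(masked_fig1, "Y", ("X",), "Y", ("X", "W"), m=10, seed=7)
        b = mi_analyze(masked_fig1, "Y", ("X",), "Y", ("X", "W"), m=10, seed=7)
        assert a.pooled_estimate == b.pooled_estimate
        assert a.per_imputation_estimates == b.per_imputation_estimates

    def test_cra_unbiased_in_mar_scenario(self, fig1):
        ests = []
        for seed in range(60):
            data = simulate_complete(fig1, 1500, seed=300 + seed)
            data = impose_missingness(data, MissingnessSpec("Y", target_missing_proportion=0.5))
            ests.append(cra_estimate(data, "Y", ("X",)).estimate("X"))
        mc_se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - 1.0) < 4 * mc_se

    def test_cra_biased_when_outcome_drives_missingness(self, fig6):
        """When the analysis outcome causes missingness of the exposure,
        complete records analysis is no longer valid."""
        ests = []
        for seed in range(40):
            data = simulate_complete(fig6, 1500, seed=500 + seed)
            data = impose_missingness(data, MissingnessSpec("X", target_missing_proportion=0.5))
            ests.append(cra_estimate(data, "Y", ("X",)).estimate("X"))
        mc_se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - 1.0) > 4 * mc_se
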