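"""Path-model construction, implied moments and Gaussian conditioning."""

import numpy as np
import pytest

from collidermi import (
    build_path_model,
    conditional_regression,
    implied_moments,
    simulate_complete,
)
from collidermi.sem_core import ModelSpecError

from conftest import random_fig1_model


class TestBuildPathModel:
    def test_fig1_preset_structure(self, fig1):
        assert set(fig1.variables) == {"Y", "X", "Z", "W", "U", "R"}
        edges = {(c, p) for (c, p) in fig1.coefficients}
        assert edges == {("Y", "X"), ("Y", "Z"), ("W", "Z"), ("W", "U"), ("R", "X"), ("R", "U")}
        assert all(v == 1.0 for v in fig1.coefficients.values())
        assert all(v == 1.0 for v in fig1.error_variances.values())
        assert fig1.role("collider") == "W"
        assert fig1.role("missingness") == "R"

    def test_self_loop_rejected(self):
        with pytest.raises(ModelSpecError, match="self-loop"):
            build_path_model({"variables": ["Y"], "edges": [["Y", "Y", 1.0]],
                              "error_variances": {"Y": 1.0}, "roles": {"missingness": "Y"}})

    def test_cycle_rejected(self):
        with pytest.raises(ModelSpecError, match="cycle"):
            build_path_model({
                "variables": ["A", "B", "R"],
                "edges": [["A", "B", 1.0], ["B", "A", 1.0]],
                "error_variances": {"A": 1.0, "B": 1.0, "R": 1.0},
                "roles": {"missingness": "R"},
            })

    @pytest.mark.parametrize("bad_var", [0.0, -1.0])
    def test_nonpositive_error_variance_rejected(self, bad_var):
        with pytest.raises(ModelSpecError, match="error variance"):
            build_path_model({"variables": ["W", "R"], "edges": [],
                              "error_variances": {"W": bad_var, "R": 1.0},
                              "roles": {"missingness": "R"}})

    def test_missing_r_role_rejected(self):
        with pytest.raises(ModelSpecError, match="missingness"):
            build_path_model({"variables": ["Y"], "edges": [], "error_variances": {"Y": 1.0}})

    def test_undeclared_variable_rejected(self):
        with pytest.raises(ModelSpecError):
            build_path_model({"variables": ["Y", "R"], "edges": [["Y", "Q", 1.0]],
                              "error_variances": {"Y": 1.0, "R": 1.0},
                              "roles": {"missingness": "R"}})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        spec = {
            "variables": ["Y", "X", "R"],
            "edges": [["Y", "X", 2.0], ["R", "X", 0.5]],
            "error_variances": {"Y": 1.0, "X": 1.0, "R": 1.0},
            "roles": {"outcome": "Y", "exposure": "X", "missingness": "R"},
        }
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(spec))
        model = build_path_model(str(path))
        assert model.coefficient("Y", "X") == 2.0
        assert model.role("missingness") == "R"


class TestImpliedMoments:
    def test_empty_graph_identity_covariance(self):
        model = build_path_model({"variables": ["A", "B", "R"], "edges": [],
                                  "error_variances": {"A": 1.0, "B": 1.0, "R": 1.0},
                                  "roles": {"missingness": "R"}})
        joint = implied_moments(model)
        np.testing.assert_allclose(joint.cov, np.eye(3))
        np.testing.assert_allclose(joint.mean, np.zeros(3))

    def test_fig1_hand_traced_moments(self, fig1_joint):
        j = fig1_joint
        assert j.var("Y") == pytest.approx(3.0)
        assert j.var("W") == pytest.approx(3.0)
        assert j.var("R") == pytest.approx(3.0)
        assert j.covariance("Y", "W") == pytest.approx(1.0)
        assert j.covariance("X", "W") == pytest.approx(0.0)
        assert j.covariance("Y", "R") == pytest.approx(1.0)
        assert j.covariance("W", "R") == pytest.approx(1.0)
        assert j.covariance("X", "R") == pytest.approx(1.0)

    def test_fig4_hand_traced_moments(self, fig4):
        j = implied_moments(fig4)
        assert j.var("Y") == pytest.approx(3.0)
        assert j.var("X") == pytest.approx(2.0)
        assert j.var("R") == pytest.approx(2.0)
        assert j.covariance("R", "W") == pytest.approx(1.0)
        assert j.covariance("X", "W") == pytest.approx(1.0)
        assert j.covariance("Y", "W") == pytest.approx(1.0)

    def test_means_propagate_through_graph(self, fig1):
        model = build_path_model("fig1")
        model = type(model)(**{**model.__dict__, "means": {"X": 2.0}})
        j = implied_moments(model)
        assert j.mean_of("X") == pytest.approx(2.0)
        assert j.mean_of("Y") == pytest.approx(2.0)  # Y <- X with coefficient 1
        assert j.mean_of("R") == pytest.approx(2.0)

    @pytest.mark.parametrize("preset", ["fig1", "fig4", "fig6", "fig8-theoretical"])
    def test_matches_monte_carlo_covariance(self, preset):
        """Implied covariance agrees with the sample covariance of draws to
        within 4 Monte-Carlo standard errors for every preset."""
        model = build_path_model(preset)
        joint = implied_moments(model)
        n = 100_000
        data = simulate_complete(model, n, seed=2024)
        sample = np.cov(data.df[list(joint.names)].to_numpy().T)
        for i in range(len(joint.names)):
            for k in range(i, len(joint.names)):
                # MC standard error of a covariance of jointly normal draws
                mc_se = np.sqrt(
                    (joint.cov[i, i] * joint.cov[k, k] + joint.cov[i, k] ** 2) / n
                )
                assert abs(sample[i, k] - joint.cov[i, k]) < 4 * mc_se


class TestConditionalRegression:
    def test_fig1_y_given_xw(self, fig1_joint):
        cm_ = conditional_regression(fig1_joint, "Y", ["X", "W"])
        assert cm_.coefficient("X") == pytest.approx(1.0)
        assert cm_.coefficient("W") == pytest.approx(1 / 3)

    def test_fig1_y_given_xwr(self, fig1_joint):
        cm_ = conditional_regression(fig1_joint, "Y", ["X", "W", "R"])
        assert cm_.coefficient("X") == pytest.approx(1.2)
        assert cm_.coefficient("W") == pytest.approx(0.4)
        assert cm_.coefficient("R") == pytest.approx(-0.2)
        assert cm_.residual_variance == pytest.approx(1.6)

    def test_empty_predictor_set_gives_marginal_variance(self, fig1_joint):
        cm_ = conditional_regression(fig1_joint, "Y", [])
        assert cm_.coefficients == ()
        assert cm_.residual_variance == pytest.approx(3.0)

    def test_collider_orthogonal_to_exposure(self, fig1_joint):
        """Conditioning on W leaves the exposure coefficient unchanged
        (Cov(X, W) = 0 in the M-structure)."""
        with_w = conditional_regression(fig1_joint, "Y", ["X", "W"]).coefficient("X")
        without = conditional_regression(fig1_joint, "Y", ["X"]).coefficient("X")
        assert with_w == pytest.approx(without)

    def test_collinear_predictors_rejected(self, fig1):
        model = fig1.with_error_variances({"Y": 1e-14})  # still > 0 but degenerate
        with pytest.raises(Exception):
            conditional_regression(implied_moments(model), "X", ["Y", "Z"])
            # Y ~ X + Z exactly, so (Y, Z) given X is singular with X as target's twin
            conditional_regression(implied_moments(model), "W", ["Y", "X", "Z"])

    def test_residual_variance_monotone_in_predictors(self):
        """Adding predictors never increases the residual variance."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            joint = implied_moments(random_fig1_model(rng))
            order = ["X", "W", "R", "Z", "U"]
            residuals = [
                conditional_regression(joint, "Y", order[:k]).residual_variance
                for k in range(len(order) + 1)
            ]
            assert all(a >= b - 1e-10 for a, b in zip(residuals, residuals[1:]))

    def test_topological_order_deterministic(self, fig1):
        assert fig1.topological_order() == ("X", "Z", "Y", "U", "W", "R")
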