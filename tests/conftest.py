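import numpy as np
import pytest

from collidermi import build_path_model, implied_moments


@pytest.fixture(scope="session")
def fig1():
    return build_path_model("fig1")


@pytest.fixture(scope="session")
def fig4():
    return build_path_model("fig4")


@pytest.fixture(scope="session")
def fig6():
    return build_path_model("fig6")


@pytest.fixture(scope="session")
def fig1_joint(fig1):
    return implied_moments(fig1)


def random_fig1_model(rng: np.random.Generator):
    """Fig-1-shaped model with random coefficients in [-2, 2] and error
    variances in [0.25, 4]."""
    model = build_path_model("fig1")
    coefs = {edge: float(rng.uniform(-2, 2)) for edge in model.coefficients}
    evs = {v: float(rng.uniform(0.25, 4.0)) for v in model.variables}
    return model.with_coefficients(coefs).with_error_variances(evs)
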