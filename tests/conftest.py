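import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from plumeloc import LikelihoodField, PlumeParams, PriorBox


@pytest.fixture(scope="session")
def params():
    """Canonical fitted anisotropic plume parameters."""
    return PlumeParams()


@pytest.fixture(scope="session")
def iso_params():
    return PlumeParams(isotropic=True)


@pytest.fixture(scope="session")
def prior(params):
    lam = params.lambda_scale
    return PriorBox(lam, 15 * lam, -150.0, 150.0)


@pytest.fixture(scope="session")
def small_field(params):
    """Coarse gridded field over a 15-lambda domain (fast MAP tests)."""
    lam = params.lambda_scale
    x = np.linspace(lam, 15 * lam, 68)
    y = np.linspace(-150.0, 150.0, 21)
    return LikelihoodField.from_params(params, x, y)


@pytest.fixture(scope="session")
def fit_grid(params):
    """The 60x40 near-field grid used for parameter-recovery studies."""
    lam = params.lambda_scale
    x = np.linspace(1.2 * lam, 6 * lam, 60)
    y = np.linspace(-55.0, 55.0, 40)
    return LikelihoodField.from_params(params, x, y)
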