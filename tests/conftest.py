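import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gnladc import CoilModel, default_model  # noqa: E402


@pytest.fixture(scope="session")
def model() -> CoilModel:
    """The shipped representative coil model."""
    return default_model()


@pytest.fixture(scope="session")
def linear_model() -> CoilModel:
    """Ideal linear gradients (no nonlinearity anywhere)."""
    return CoilModel.linear()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_orthonormal_triad(rng: np.random.Generator) -> np.ndarray:
    """Random rotation matrix via QR decomposition (rows orthonormal)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
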