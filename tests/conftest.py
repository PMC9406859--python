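import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retinopatch import StubBackend

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stub_backend():
    """Default-dimension stub: 1000 fc + 1920 pool features."""
    return StubBackend()


@pytest.fixture(scope="session")
def toy_backend():
    """Tiny stub for dimension-law tests (fc 4, pool 6, D = 90)."""
    return StubBackend(fc_dim=4, pool_dim=6, input_side=8, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_canvas(rng, n=1):
    """Random uint8 256x256x3 images."""
    return rng.integers(0, 256, size=(n, 256, 256, 3), dtype=np.uint8)
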