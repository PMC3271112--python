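import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemorph.stain import StainBasis
from hemorph.synthetic_data import generate_reference_tile

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis() -> StainBasis:
    return StainBasis.default_he()


@pytest.fixture(scope="session")
def reference():
    """The shipped synthetic stain-normalization reference tile."""
    return generate_reference_tile()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
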