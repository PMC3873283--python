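import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octseg.edges import default_profiles

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One zero-noise default-geometry phantom shared across tests."""
    from octseg.phantom import generate_bscan, random_phantom_spec

    spec = random_phantom_spec(3, speckle_variance=0.0)
    image, truth = generate_bscan(spec)
    return spec, image, truth
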