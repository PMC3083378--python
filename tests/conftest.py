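import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carotidseg import PhantomSpec, generate_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(texture_sd=0.0, n_frames=1, radius_amplitude_px=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    frames, truth = generate_phantom(noiseless_spec)
    return noiseless_spec, frames, truth


@pytest.fixture(scope="session")
def textured_phantom():
    spec = PhantomSpec(texture_sd=8.0, n_frames=3, radius_amplitude_px=1.0, rng_seed=7)
    frames, truth = generate_phantom(spec)
    return spec, frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
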