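import numpy as np
import pytest

from sutureplan import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with the noise turned off."""
    spec = PhantomSpec(noise_sd=0.0, seed=7)
    stack, gt = generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom at the default sensor noise (sd 0.01)."""
    spec = PhantomSpec(noise_sd=0.01, seed=7)
    stack, gt = generate_phantom(spec)
    return spec, stack, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
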