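import numpy as np
import pytest

from mvct.geometry import CTVolume
from mvct.synthetic import DoseSpec, PhantomSpec, generate_phantom, simulate_low_dose


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_volume(rng):
    return CTVolume(rng.normal(size=(4, 5, 6)), spacing=(2.5, 1.0, 1.0), volume_id="rv")


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(PhantomSpec(shape=(12, 32, 32), seed=7))


@pytest.fixture(scope="session")
def gaussian_pair():
    """A (low, high) pair using the fast image-domain noise mode."""
    hd = generate_phantom(PhantomSpec(shape=(12, 32, 32), seed=3))
    ld = simulate_low_dose(hd, DoseSpec(noise_mode="image_gaussian", seed=5))
    return ld, hd
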