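import numpy as np
import pytest

from morphrel import phantoms


@pytest.fixture(scope="session")
def icosphere50():
    """Radius-50 icosphere reused across mesh tests."""
    return phantoms.icosphere(radius=50.0, subdivisions=4)


@pytest.fixture(scope="session")
def bumpy_pair():
    """Bumpy spheres at two amplitudes, same seed, generator defaults."""
    low = phantoms.bumpy_sphere(phantoms.BumpySphereSpec(amplitude=2.0, seed=1))
    high = phantoms.bumpy_sphere(phantoms.BumpySphereSpec(amplitude=5.0, seed=1))
    return low, high


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
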