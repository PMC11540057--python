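import numpy as np
import pytest

from wfseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom spec used throughout the suite."""
    return PhantomSpec(volume_shape=(32, 32, 32), region_radii=(9.0, 6.0, 3.0), seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = PhantomSpec(
        volume_shape=(32, 32, 32), region_radii=(9.0, 6.0, 3.0), noise_sd=0.0, seed=11
    )
    return generate_phantom(spec)
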