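import numpy as np
import pytest

from segqc.phantoms import PhantomSpec, generate_lung_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small anisotropic phantom grid used across the suite."""
    return PhantomSpec(shape=(64, 64, 32), seed=7)


@pytest.fixture(scope="session")
def phantom(small_spec):
    return generate_lung_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)
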