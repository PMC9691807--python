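import numpy as np
import pytest

from breathsync import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_case():
    """One noiseless phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noisy_case():
    return generate_phantom(PhantomSpec(seed=7, noise="poisson"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
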