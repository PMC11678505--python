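import numpy as np
import pytest

from petrr.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One amyloid-positive phantom on the default 64^3 grid."""
    return generate_phantom(PhantomSpec(seed=7, amyloid_burden=1.0))


@pytest.fixture(scope="session")
def midburden_phantom():
    return generate_phantom(PhantomSpec(seed=3, amyloid_burden=0.6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
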