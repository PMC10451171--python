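import numpy as np
import pytest

from airway2d.phantom import PhantomSpec, desk_spec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 96x96 phantom with known constriction row."""
    return generate_phantom(desk_spec(96))


@pytest.fixture(scope="session")
def native_phantom():
    """One full-resolution (910x910) phantom."""
    return generate_phantom(PhantomSpec(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
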