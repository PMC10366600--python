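import numpy as np
import pytest

from ethosim.ethogram import make_composite_preset, make_state_preset
from ethosim.simulator import generate_dataset


@pytest.fixture(scope="session")
def state_spec():
    return make_state_preset()


@pytest.fixture(scope="session")
def composite_spec():
    return make_composite_preset()


@pytest.fixture(scope="session")
def small_state_series(state_spec):
    """A short labeled series from the state preset, shared across tests."""
    return generate_dataset(state_spec, 120, seed=42)


@pytest.fixture(scope="session")
def small_composite_series(composite_spec):
    return generate_dataset(composite_spec, 120, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
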