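import numpy as np
import pytest

from megcascade.design import generate_design
from megcascade.pipeline import active_epochs, active_target
from megcascade.synthetic import simulate_behavior, simulate_epochs


@pytest.fixture(scope="session")
def small_table():
    """72-trial design (64 active) with simulated behavior."""
    table = generate_design(n_blocks=2, trials_per_block=36,
                            passive_per_block=4, seed=11)
    return simulate_behavior(table, seed=12)


@pytest.fixture(scope="session")
def small_epochs(small_table):
    """Matching default-spec epochs at 50 Hz, 10 channels."""
    return simulate_epochs(small_table, None, n_channels=10, noise_sd=1.0,
                           space="sensor", seed=13, sfreq=50.0,
                           tmin_ms=-100.0, tmax_ms=700.0)


@pytest.fixture(scope="session")
def small_active(small_table, small_epochs):
    """(epochs, table) restricted helpers for decoding tests."""
    return active_epochs(small_epochs, small_table), small_table


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
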