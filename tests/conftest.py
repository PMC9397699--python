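import numpy as np
import pytest

from chaolle.synthetic import (ChaoticSystemSpec, ERDConfig,
                               generate_erd_epochs, simulate_map_series)


@pytest.fixture(scope="session")
def logistic_series():
    """5000-point chaotic logistic orbit (r=4), transient removed."""
    spec = ChaoticSystemSpec("logistic", n_samples=5100,
                             transient_discard=100, initial_state=[0.2])
    return simulate_map_series(spec)


@pytest.fixture(scope="session")
def henon_series():
    spec = ChaoticSystemSpec("henon", n_samples=5100, transient_discard=100)
    return simulate_map_series(spec)


@pytest.fixture(scope="session")
def sine_series():
    """Pure sinusoid sampled 64 points per cycle."""
    return np.sin(2 * np.pi * np.arange(3000) / 64)


@pytest.fixture(scope="session")
def small_epochs():
    """Planted-effect two-class epochs, small enough for unit tests."""
    return generate_erd_epochs(ERDConfig(n_epochs_per_class=20, seed=5))


@pytest.fixture(scope="session")
def null_epochs():
    """No planted effect: identical chaoticity and no ERD."""
    return generate_erd_epochs(ERDConfig(
        n_epochs_per_class=20, erd_depth=0.0,
        chaotic_r=(3.8, 3.8), chaotic_mix=(0.8, 0.8), seed=6))
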