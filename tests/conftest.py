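import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import serialbias as sb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def walk() -> sb.DistanceSequence:
    """A default 130-trial random-walk stimulus sequence."""
    return sb.generate_random_walk(seed=11)


@pytest.fixture(scope="session")
def static_table(walk):
    """Static-observer reproductions (w = 0.5) on the default walk."""
    return sb.simulate_static(walk, w=0.5, noise_sd=0.05, seed=12)


@pytest.fixture(scope="session")
def shuffled_table(static_table):
    """Pair-shuffled (no-autocorrelation) counterpart of static_table."""
    return sb.shuffle_pairs(static_table, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
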