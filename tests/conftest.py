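import numpy as np
import pytest

from trigame import StrategyState, baseline_parameters
from trigame.scenarios import random_parameters


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)


def random_interior_state(rng, lo=0.05, hi=0.95):
    return StrategyState(*rng.uniform(lo, hi, size=3))


def random_parameter_sets(n, seed0=0):
    """n seeded parameter sets, deterministic across runs."""
    return [random_parameters(seed0 + k) for k in range(n)]
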