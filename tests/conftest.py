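import numpy as np
import pandas as pd
import pytest

from senesurv.config import SimConfig
from senesurv.synthetic_data import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient cohort with cells, shared across read-only tests."""
    cfg = SimConfig(n_patients=30, seed=7, cells_per_core=80.0, cd8_per_core=40.0)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, event_rate_scale=0.02, window=120.0):
    """Exponential event times with uniform administrative censoring."""
    t = rng.exponential(1.0 / event_rate_scale, n)
    c = rng.uniform(0, window, n)
    return np.minimum(t, c), (t <= c).astype(int)


@pytest.fixture()
def survival_factory():
    return random_survival
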