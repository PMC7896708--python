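import numpy as np
import pandas as pd
import pytest

from resistsurv.synthetic_data import SimConfig, simulate_interactions


@pytest.fixture(scope="session")
def small_study():
    """One medium synthetic study shared by engine tests (read-only)."""
    cfg = SimConfig(n_records=1200, lambda0=0.01, n_species=60, n_insecticides=40)
    return simulate_interactions(cfg, 42)


@pytest.fixture(scope="session")
def design(small_study):
    return small_study[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cox_data():
    """20 records, distinct event times, two covariates; for likelihood oracles."""
    r = np.random.default_rng(7)
    n = 20
    x1 = r.normal(size=n)
    x2 = r.normal(size=n)
    # distinct durations -> tie-free
    dur = np.sort(r.uniform(1, 50, n))
    np.random.default_rng(8).shuffle(dur)
    event = (r.random(n) < 0.7).astype(int)
    return pd.DataFrame({"x1": x1, "x2": x2, "duration": dur, "event": event})
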