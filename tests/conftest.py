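import numpy as np
import pandas as pd
import pytest

from accelstates.core_io import censor_bouts
from accelstates.dba_metrics import MetricConfig, compute_metrics, decompose
from accelstates.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_pair():
    """One hour of the default synthetic preset (trace + ethogram), seed 7."""
    cfg = SimulationConfig(total_duration=3600.0, random_seed=7)
    trace, eth = simulate(cfg)
    return trace, eth


@pytest.fixture(scope="session")
def labelled_table(sim_pair):
    """Training-mode metric table for the session trace (9-s smoother)."""
    trace, eth = sim_pair
    censored = censor_bouts(eth, sample_period=trace.sample_period)
    dyn = decompose(trace, 9)
    return compute_metrics(dyn, MetricConfig(), bouts=censored)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
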