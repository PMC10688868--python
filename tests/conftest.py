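import numpy as np
import pandas as pd
import pytest

import nutricohort as nc
from nutricohort import cgm


@pytest.fixture(scope="session")
def default_config():
    return nc.SimulationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-participant cohort-B dataset used across modules."""
    cfg = nc.SimulationConfig(n_participants=30, seed=2, cohort_fraction_c=0.0)
    return nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_traces(small_cohort):
    return cgm.traces_from_frame(small_cohort.glucose)


def make_trace(values, start="2021-03-01", freq="15min", pid="P0"):
    """Build a GlucoseTrace from raw values on a regular grid."""
    idx = pd.date_range(start, periods=len(values), freq=freq)
    return cgm.GlucoseTrace(pid, pd.Series(np.asarray(values, dtype=float),
                                           index=idx))


@pytest.fixture(scope="session")
def random_traces():
    """100 short noisy meal-driven traces for oracle-equivalence checks."""
    traces = []
    for i in range(100):
        cfg = nc.SimulationConfig(seed=100 + i)
        rng = np.random.default_rng(100 + i)
        start = pd.Timestamp("2021-05-03")
        n_days = 2
        meals = nc.synthetic.generate_meal_schedule(start, n_days, cfg, rng)
        df = nc.synthetic.generate_glucose_trace(start, n_days, meals, cfg, rng)
        traces.append(cgm.GlucoseTrace(
            f"R{i}", pd.Series(df["glucose_mmol_l"].to_numpy(),
                               index=pd.DatetimeIndex(df["timestamp"]))))
    return traces
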