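import numpy as np
import pytest

import dcenrich as d
from dcenrich.synthetic import write_simulation


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A small simulated study on disk: RR CSVs, cohort.csv, truth.json."""
    out = tmp_path_factory.mktemp("sim")
    params = d.CohortGenParams(n_patients=60, rr_duration=900.0, seed=123)
    write_simulation(params, out)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """In-memory synthetic cohort (150 patients, 10-min Holter each)."""
    return d.generate_cohort(
        d.CohortGenParams(n_patients=150, rr_duration=600.0, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_nn(intervals, gaps=None, start=0.0):
    """Build an NNSeries with consistent beat times from interval values (ms)."""
    intervals = np.asarray(intervals, dtype=float)
    times = start + np.concatenate([[0.0], np.cumsum(intervals[:-1]) / 1000.0])
    if gaps is None:
        gaps = np.zeros(len(intervals), dtype=bool)
    return d.NNSeries("test", times, intervals, np.asarray(gaps, dtype=bool))
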