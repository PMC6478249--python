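import numpy as np
import pandas as pd
import pytest

import pitkit as pk


@pytest.fixture(scope="session")
def params():
    return pk.default_params()


@pytest.fixture(scope="session")
def cohort_exp2():
    """One default Experiment-2 cohort (35 subjects, all phases)."""
    return pk.sample_cohort(pk.make_design(2), seed=20240)


@pytest.fixture(scope="session")
def summary_exp2(cohort_exp2):
    return pk.summarize(cohort_exp2.events, phase=3)


@pytest.fixture(scope="session")
def cohort_exp1():
    return pk.sample_cohort(pk.make_design(1), seed=20241)


def make_events(cells, n_trials=4, presses_per_trial=10, all_win=True,
                latency=0.5, subject=0, phase=3):
    """Hand-built event log: fixed press count and outcome in every trial."""
    rows = []
    for cs, frame, go in cells:
        for idx in range(n_trials):
            for k in range(presses_per_trial):
                rows.append((subject, phase, 1, idx, frame, go, cs, "press",
                             latency + 0.1 * k, "1"))
            rows.append((subject, phase, 1, idx, frame, go, cs, "outcome", 5.0,
                         "win" if all_win else "incomplete"))
    from pitkit.cohort import EVENT_COLUMNS
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
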