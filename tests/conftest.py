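import numpy as np
import pandas as pd
import pytest

from mmrisk import SimulationConfig, simulate_challenge


def make_survival(times, events, patient_ids=None, os_times=None, os_events=None):
    """Survival DataFrame helper for hand-built examples."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if patient_ids is None:
        patient_ids = [f"p{i:02d}" for i in range(len(times))]
    return pd.DataFrame(
        {
            "pfs_months": times,
            "pfs_event": events,
            "os_months": times if os_times is None else np.asarray(os_times, float),
            "os_event": events if os_events is None else np.asarray(os_events, int),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cohorts=2, patients_per_cohort=[120, 150], n_genes=60, seed=3
    )


@pytest.fixture(scope="session")
def small_challenge():
    """4 training + 2 validation cohorts of 200 patients, 40 genes."""
    config = SimulationConfig(
        n_cohorts=6, patients_per_cohort=[200] * 6, n_genes=40, seed=17
    )
    train, validation = simulate_challenge(config, 4, 2)
    return config, train, validation
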