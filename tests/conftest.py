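import datetime as dt

import pandas as pd
import pytest

from inhalytics import SimulationParams, StudyConfig, simulate_cohort


def make_events(rows):
    """Build an event DataFrame from (patient_id, iso_timestamp) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_registry(rows):
    """Build a registry DataFrame from (patient_id, regimen, sex, age)."""
    df = pd.DataFrame(rows, columns=["patient_id", "regimen", "sex", "age"])
    df["age"] = df["age"].astype("Int64")
    return df


@pytest.fixture
def config():
    return StudyConfig(cutoff_date=dt.date(2018, 11, 11))


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderately sized seeded default-model cohort shared across tests."""
    params = SimulationParams(n_patients=150, horizon_days=150, seed=11)
    return params, simulate_cohort(params)
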