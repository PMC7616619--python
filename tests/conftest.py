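from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from dmard_monitor import MonitoringData, SimulationConfig, simulate_dataset
from dmard_monitor.data import PATIENT_COLUMNS

PATIENT_DEFAULTS = {
    "practice_id": "gp0001",
    "age_band": "50-59",
    "sex": "female",
    "ethnicity": "White",
    "region": "East",
    "imd_quintile": 3,
    "rural_urban": 3,
    "dementia": False,
    "learning_disability": False,
    "serious_mental_illness": False,
    "care_home": False,
    "housebound": False,
    "registration_start": "2010-01-01",
    "death_date": None,
}


def make_patient(patient_id: str, **overrides) -> dict:
    row = {"patient_id": patient_id, **PATIENT_DEFAULTS}
    row.update(overrides)
    return row


def build_data(patients, prescriptions=(), tests=()) -> MonitoringData:
    """MonitoringData from row dicts / (pid, drug, date) / (pid, test, date)."""
    pframe = pd.DataFrame(list(patients), columns=PATIENT_COLUMNS)
    for col in ("registration_start", "death_date"):
        pframe[col] = pd.to_datetime(pframe[col])
    for col in ("imd_quintile", "rural_urban"):
        pframe[col] = pframe[col].astype("Int64")
    rx = pd.DataFrame(
        [
            {"patient_id": p, "drug": d, "issue_date": pd.Timestamp(when)}
            for p, d, when in prescriptions
        ],
        columns=["patient_id", "drug", "issue_date"],
    )
    rx["issue_date"] = pd.to_datetime(rx["issue_date"])
    tt = pd.DataFrame(
        [
            {"patient_id": p, "test_type": t, "date": pd.Timestamp(when)}
            for p, t, when in tests
        ],
        columns=["patient_id", "test_type", "date"],
    )
    tt["date"] = pd.to_datetime(tt["date"])
    return MonitoringData(patients=pframe, prescriptions=rx, tests=tt)


def quarterly_issues(patient_id, drug, start, n, gap_days=84):
    """n prescription issues at a fixed gap from ``start``."""
    start = pd.Timestamp(start)
    return [
        (patient_id, drug, start + pd.Timedelta(days=gap_days * k))
        for k in range(n)
    ]


@pytest.fixture(scope="session")
def small_sim() -> MonitoringData:
    """Default-condition simulation, modest size, for integration checks."""
    return simulate_dataset(SimulationConfig(n_patients=800, n_practices=20, seed=42))


@pytest.fixture(scope="session")
def calibration_config() -> SimulationConfig:
    """Pure miss-mechanism run: no practice/subgroup/frailty effects.

    With a single drug and no random effects the configured per-window
    miss probability is exactly the estimand of the monthly indicator.
    """
    return SimulationConfig(
        n_patients=5000,
        n_practices=50,
        seed=2024,
        drug_prevalence={"methotrexate": 1.0},
        combination_therapy_rate=0.0,
        discontinuation_hazard=0.0,
        practice_effect_sd=0.0,
        patient_frailty_sd=0.0,
        subgroup_effects={},
        annual_death_rate=0.0,
    )


@pytest.fixture(scope="session")
def calibration_sim(calibration_config) -> MonitoringData:
    return simulate_dataset(calibration_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
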