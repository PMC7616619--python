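"""In-memory container and CSV round-trip for the three event tables.

All dates are ISO-8601 in the CSV files.  ``patients.csv`` carries one row
per patient with demographics, subgroup flags and registration/death dates;
``prescriptions.csv`` one row per issued prescription; ``tests.csv`` one
row per recorded monitoring test.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError

PATIENT_COLUMNS = [
    "patient_id",
    "practice_id",
    "age_band",
    "sex",
    "ethnicity",
    "region",
    "imd_quintile",
    "rural_urban",
    "dementia",
    "learning_disability",
    "serious_mental_illness",
    "care_home",
    "housebound",
    "registration_start",
    "death_date",
]
PRESCRIPTION_COLUMNS = ["patient_id", "drug", "issue_date"]
TEST_COLUMNS = ["patient_id", "test_type", "date"]

_FILES = {
    "patients": "patients.csv",
    "prescriptions": "prescriptions.csv",
    "tests": "tests.csv",
}


@dataclass
class MonitoringData:
    """Patient, prescription and test tables for one analysis run."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    tests: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise DataError(f"patients table is missing columns {missing}")
        for name, cols in (
            ("prescriptions", PRESCRIPTION_COLUMNS),
            ("tests", TEST_COLUMNS),
        ):
            table = getattr(self, name)
            missing = [c for c in cols if c not in table.columns]
            if missing:
                raise DataError(f"{name} table is missing columns {missing}")

    # ------------------------------------------------------------------
    @classmethod
    def load(cls, directory) -> "MonitoringData":
        directory = Path(directory)
        frames = {}
        for key, fname in _FILES.items():
            path = directory / fname
            if not path.exists():
                raise DataError(f"missing input file: {path}")
            frames[key] = pd.read_csv(path)
        patients = frames["patients"]
        for col in ("registration_start", "death_date"):
            patients[col] = pd.to_datetime(patients[col], format="ISO8601")
        for col in ("imd_quintile", "rural_urban"):
            patients[col] = patients[col].astype("Int64")
        for col in ("dementia", "learning_disability", "serious_mental_illness",
                    "care_home", "housebound"):
            patients[col] = patients[col].astype(bool)
        prescriptions = frames["prescriptions"]
        prescriptions["issue_date"] = pd.to_datetime(
            prescriptions["issue_date"], format="ISO8601"
        )
        tests = frames["tests"]
        tests["date"] = pd.to_datetime(tests["date"], format="ISO8601")
        return cls(patients=patients, prescriptions=prescriptions, tests=tests)

    def save(self, directory) -> dict:
        """Write the three CSVs; returns {filename: path}."""
        directory = Path(directory)
        os.makedirs(directory, exist_ok=True)
        written = {}
        for key, fname in _FILES.items():
            table = getattr(self, key).copy()
            for col in table.columns:
                if pd.api.types.is_datetime64_any_dtype(table[col]):
                    table[col] = table[col].dt.strftime("%Y-%m-%d")
            path = directory / fname
            table.to_csv(path, index=False)
            written[fname] = path
        return written
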