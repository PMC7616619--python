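"""Independent brute-force reference for the monthly indicator counts.

Re-derives, with plain Python loops and its own calendar arithmetic,
which patients are eligible, on-drug and missing monitoring at an index
month.  Deliberately shares no code with the package engine so it can
serve as an oracle for numerator/denominator equivalence.
"""

from __future__ import annotations

import calendar
from datetime import date, datetime

REQUIRED = {
    "azathioprine": ("FBC", "LFT", "UE"),
    "leflunomide": ("FBC", "LFT", "UE", "BP"),
    "methotrexate": ("FBC", "LFT", "UE"),
}


def _to_date(value):
    if value is None:
        return None
    if isinstance(value, str):
        return date.fromisoformat(value)
    if isinstance(value, datetime):  # includes pandas Timestamp
        return value.date()
    return value


def _month_end(year: int, month: int) -> date:
    return date(year, month, calendar.monthrange(year, month)[1])


def _shift_clamped(d: date, months_back: int) -> date:
    total = d.year * 12 + (d.month - 1) - months_back
    y, m0 = divmod(total, 12)
    m = m0 + 1
    return date(y, m, min(d.day, calendar.monthrange(y, m)[1]))


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return value != value  # NaN / NA
    except Exception:
        return False


def brute_force_counts(data, year, month, drugs, tests=None):
    """(numerator, denominator) for one month, by per-patient enumeration."""
    index_date = _month_end(year, month)
    lb_year, lb_month0 = divmod(year * 12 + (month - 1) - 2, 12)
    lookback_first = date(lb_year, lb_month0 + 1, 1)
    minus3 = _shift_clamped(index_date, 3)
    minus6 = _shift_clamped(index_date, 6)

    rx_by_patient: dict = {}
    for row in data.prescriptions.to_dict("records"):
        rx_by_patient.setdefault(row["patient_id"], []).append(
            (row["drug"], _to_date(row["issue_date"]))
        )
    tests_by_patient: dict = {}
    for row in data.tests.to_dict("records"):
        tests_by_patient.setdefault(row["patient_id"], []).append(
            (row["test_type"], _to_date(row["date"]))
        )

    numerator = denominator = 0
    for patient in data.patients.to_dict("records"):
        death = _to_date(patient.get("death_date"))
        if not _is_missing(death) and death is not None and death <= index_date:
            continue
        reg = _to_date(patient.get("registration_start"))
        if _is_missing(reg) or reg is None or reg > index_date:
            continue
        if any(
            _is_missing(patient.get(f))
            for f in ("age_band", "sex", "imd_quintile", "rural_urban")
        ):
            continue
        issues = rx_by_patient.get(patient["patient_id"], [])
        events = tests_by_patient.get(patient["patient_id"], [])
        for drug in drugs:
            recent = any(
                d == drug and minus3 < when <= index_date for d, when in issues
            )
            earlier = any(
                d == drug and minus6 < when <= minus3 for d, when in issues
            )
            if not (recent and earlier):
                continue
            required = [
                t for t in REQUIRED[drug] if tests is None or t in tests
            ]
            if not required:
                continue
            denominator += 1
            missed = False
            for t in required:
                seen = any(
                    tt == t and lookback_first <= when <= index_date
                    for tt, when in events
                )
                if not seen:
                    missed = True
                    break
            if missed:
                numerator += 1
    return numerator, denominator
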