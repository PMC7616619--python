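"""Cohort selection: who is eligible, and who counts as on-drug, each month.

A patient is *on* a drug at an index month if they have at least two
prescription issues: one within the 3 calendar months before the index
date and another between 3 and 6 calendar months before it.  This mirrors
repeat prescribing in English general practice, where the large majority
of repeat prescriptions cover 3 months or less, so two staggered issues
indicate established ongoing therapy.

The index date for a named month is the last day of that month; month
arithmetic is calendar-based with end-of-month clamping (31 May minus
3 months is 28/29 February).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date, datetime

import pandas as pd

from .errors import ConfigurationError, DataError

#: Monitoring tests required every 3 months for each drug.  The
#: blood-pressure check applies to leflunomide only; weight is excluded
#: because it is not consistently listed as a requirement and is taken
#: alongside BP, which therefore proxies physical checks.
DRUG_REQUIREMENTS: dict[str, frozenset] = {
    "azathioprine": frozenset({"FBC", "LFT", "UE"}),
    "leflunomide": frozenset({"FBC", "LFT", "UE", "BP"}),
    "methotrexate": frozenset({"FBC", "LFT", "UE"}),
}

TEST_TYPES = ("FBC", "LFT", "UE", "BP")
BLOOD_TESTS = ("FBC", "LFT", "UE")

#: Fields that must be non-missing for a patient to enter any denominator.
CORE_FIELDS = ("age_band", "sex", "imd_quintile", "rural_urban")


def _clamped_month_shift(year: int, month: int, day: int, months: int) -> date:
    """Shift a calendar date by ``months``, clamping the day to month end."""
    m = year * 12 + (month - 1) + months
    y, m = divmod(m, 12)
    m += 1
    return date(y, m, min(day, calendar.monthrange(y, m)[1]))


@dataclass(frozen=True, order=True)
class IndexMonth:
    """A named measurement month with its 3-calendar-month lookback."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1-12, got {self.month}")

    @classmethod
    def from_string(cls, text: str) -> "IndexMonth":
        try:
            y, m = text.split("-")
            return cls(int(y), int(m))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"expected 'YYYY-MM', got {text!r}") from exc

    @classmethod
    def coerce(cls, value) -> "IndexMonth":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls.from_string(value)
        if isinstance(value, (date, datetime)):
            return cls(value.year, value.month)
        raise ValueError(f"cannot interpret {value!r} as a month")

    @property
    def index_date(self) -> date:
        """Last day of the named month (the search date)."""
        return date(
            self.year, self.month, calendar.monthrange(self.year, self.month)[1]
        )

    @property
    def lookback_start(self) -> date:
        """First day of the month two months earlier (3-month window)."""
        first = _clamped_month_shift(self.year, self.month, 1, -2)
        return first

    def minus_months(self, n: int) -> date:
        """Index date shifted back ``n`` calendar months, day clamped."""
        d = self.index_date
        return _clamped_month_shift(d.year, d.month, d.day, -n)

    def shift(self, months: int) -> "IndexMonth":
        m = self.year * 12 + (self.month - 1) + months
        y, m = divmod(m, 12)
        return IndexMonth(y, m + 1)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start, end) -> list[IndexMonth]:
    """Inclusive list of months from ``start`` to ``end``."""
    start = IndexMonth.coerce(start)
    end = IndexMonth.coerce(end)
    if start > end:
        raise ValueError(f"start month {start} is after end month {end}")
    out = []
    cur = start
    while cur <= end:
        out.append(cur)
        cur = cur.shift(1)
    return out


# ---------------------------------------------------------------------------
# scalar predicates


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        return date.fromisoformat(value)
    if isinstance(value, pd.Timestamp):
        return value.date()
    raise TypeError(f"not a date: {value!r}")


def eligible(patient, index: IndexMonth) -> bool:
    """True iff the patient can enter any denominator at ``index``.

    Requires: alive at the index date, registered by the index date, and
    non-missing age band, sex, IMD quintile and rural-urban class.  Age
    bands span 18-120 years, so a present band satisfies the age rule.
    """
    index = IndexMonth.coerce(index)
    pid = patient.get("patient_id", "<unknown>")
    death = patient.get("death_date")
    reg = patient.get("registration_start")
    try:
        if not pd.isna(death) and _as_date(death) <= index.index_date:
            return False
        if pd.isna(reg) or _as_date(reg) > index.index_date:
            return False
    except (TypeError, ValueError) as exc:
        raise DataError(f"malformed date in patient record {pid!r}: {exc}") from exc
    for fieldname in CORE_FIELDS:
        if pd.isna(patient.get(fieldname)):
            return False
    return True


def on_drug(prescriptions, drug: str, index: IndexMonth) -> bool:
    """True iff one patient's issues show established therapy at ``index``.

    ``prescriptions`` is that patient's prescription table (or an iterable
    of (drug, issue_date) pairs).  Requires at least one issue of ``drug``
    in ``(index_date - 3 months, index_date]`` and at least one in
    ``(index_date - 6 months, index_date - 3 months]``.
    """
    index = IndexMonth.coerce(index)
    if drug not in DRUG_REQUIREMENTS:
        raise ConfigurationError(f"unknown drug {drug!r}")
    if isinstance(prescriptions, pd.DataFrame):
        rows = prescriptions[prescriptions["drug"] == drug]
        dates = [_as_date(d) for d in rows["issue_date"]]
    else:
        dates = [_as_date(d) for drg, d in prescriptions if drg == drug]
    d0 = index.index_date
    d3 = index.minus_months(3)
    d6 = index.minus_months(6)
    recent = any(d3 < d <= d0 for d in dates)
    earlier = any(d6 < d <= d3 for d in dates)
    return recent and earlier


# ---------------------------------------------------------------------------
# vectorised cohort extraction


def eligible_ids(patients: pd.DataFrame, index: IndexMonth) -> set:
    """Set of patient_ids satisfying :func:`eligible` (vectorised)."""
    index = IndexMonth.coerce(index)
    idx = pd.Timestamp(index.index_date)
    alive = patients["death_date"].isna() | (patients["death_date"] > idx)
    registered = patients["registration_start"].notna() & (
        patients["registration_start"] <= idx
    )
    complete = pd.Series(True, index=patients.index)
    for fieldname in CORE_FIELDS:
        complete &= patients[fieldname].notna()
    return set(patients.loc[alive & registered & complete, "patient_id"])


def on_drug_ids(prescriptions: pd.DataFrame, drug: str, index: IndexMonth) -> set:
    """Set of patient_ids satisfying :func:`on_drug` for ``drug``."""
    index = IndexMonth.coerce(index)
    if drug not in DRUG_REQUIREMENTS:
        raise ConfigurationError(f"unknown drug {drug!r}")
    rx = prescriptions[prescriptions["drug"] == drug]
    d0 = pd.Timestamp(index.index_date)
    d3 = pd.Timestamp(index.minus_months(3))
    d6 = pd.Timestamp(index.minus_months(6))
    issue = rx["issue_date"]
    recent = set(rx.loc[(issue > d3) & (issue <= d0), "patient_id"])
    earlier = set(rx.loc[(issue > d6) & (issue <= d3), "patient_id"])
    return recent & earlier


def drug_denominator(data, drug: str, index: IndexMonth) -> set:
    """Patients both eligible and on ``drug`` at ``index``."""
    index = IndexMonth.coerce(index)
    return eligible_ids(data.patients, index) & on_drug_ids(
        data.prescriptions, drug, index
    )
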