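"""Missed-monitoring indicators as monthly series with disclosure rounding.

A patient in a drug's denominator at an index month has *missed
monitoring* if any test required for that drug has no record within the
3 calendar months ending at the index date.  Indicators report the
percentage of the denominator missing, with numerator and denominator
each rounded to the nearest 5 before division (statistical disclosure
control for small counts); percentages are shown to 1 decimal place.

The overall indicator counts patient-drug pairs, so a patient on two
drugs contributes to (and can miss in) both; the overall raw denominator
is then exactly the sum of the per-drug raw denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import (
    DRUG_REQUIREMENTS,
    TEST_TYPES,
    IndexMonth,
    drug_denominator,
    eligible_ids,
    month_range,
    on_drug_ids,
)
from .config import DRUGS, SUBGROUP_COLUMNS
from .errors import ConfigurationError


def round5(count: int) -> int:
    """Nearest multiple of 5 (no ties exist for integer inputs)."""
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return int(5 * round(count / 5))


def aggregate_percentage(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, half-up to 1 decimal; NaN if empty."""
    if denominator == 0:
        return math.nan
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pp_change(rate_a: float, rate_b: float) -> float:
    """Percentage-point difference rate_b - rate_a, to 1 decimal (half-up)."""
    diff = Decimal(str(rate_b)) - Decimal(str(rate_a))
    return float(diff.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def missed_for_drug(tests, drug: str, index, test_set=None) -> bool:
    """True iff one patient misses any required test in the lookback window.

    ``tests`` is that patient's test table (or iterable of
    (test_type, date) pairs).  ``test_set`` restricts the check to the
    intersection of the drug's requirements with the given tests (used for
    per-test indicators).
    """
    index = IndexMonth.coerce(index)
    required = _required_tests(drug, test_set)
    if isinstance(tests, pd.DataFrame):
        pairs = list(zip(tests["test_type"], pd.to_datetime(tests["date"])))
    else:
        pairs = [(t, pd.Timestamp(d)) for t, d in tests]
    lb = pd.Timestamp(index.lookback_start)
    idx = pd.Timestamp(index.index_date)
    seen = {t for t, d in pairs if lb <= d <= idx}
    return any(t not in seen for t in required)


def _required_tests(drug: str, test_set=None) -> frozenset:
    if drug not in DRUG_REQUIREMENTS:
        raise ConfigurationError(f"unknown drug {drug!r}")
    required = DRUG_REQUIREMENTS[drug]
    if test_set is None:
        return required
    test_set = frozenset(test_set)
    unknown = test_set - set(TEST_TYPES)
    if unknown:
        raise ConfigurationError(f"unknown test type(s) {sorted(unknown)}")
    return required & test_set


@dataclass(frozen=True)
class MonthlyIndicatorResult:
    """One (month x scope) indicator value.

    Rounded counts are the reportable (disclosure-controlled) outputs;
    raw counts are retained for internal invariants and cumulative totals.
    """

    month: IndexMonth
    drugs: tuple
    tests: tuple | None
    group: str | None
    category: object | None
    numerator_rounded: int
    denominator_rounded: int
    percentage: float
    numerator_raw: int
    denominator_raw: int


@dataclass(frozen=True)
class CumulativeTotals:
    """Whole-period event totals and the repeat-missing ratio."""

    total_events: int
    total_denominator_events: int
    unique_patients: int

    @property
    def repeat_ratio(self) -> float:
        if self.unique_patients == 0:
            return math.nan
        return self.total_events / self.unique_patients


class IndicatorEngine:
    """Computes indicators over one dataset, caching per-month scans.

    The per-month scan derives, once, each drug's denominator and the set
    of patients covered by each test type in the month's lookback window;
    every scope (overall, per drug, per test, per subgroup, per practice)
    is then a cheap set restriction.
    """

    def __init__(self, data):
        self.data = data
        self._scans: dict[IndexMonth, tuple[dict, dict]] = {}

    def _scan(self, index: IndexMonth):
        if index not in self._scans:
            den = {d: drug_denominator(self.data, d, index) for d in DRUGS}
            tests = self.data.tests
            lb = pd.Timestamp(index.lookback_start)
            idx = pd.Timestamp(index.index_date)
            window = tests[(tests["date"] >= lb) & (tests["date"] <= idx)]
            cov = {
                t: set(window.loc[window["test_type"] == t, "patient_id"])
                for t in TEST_TYPES
            }
            self._scans[index] = (den, cov)
        return self._scans[index]

    def raw_counts(self, index, drugs=DRUGS, tests=None, restrict_ids=None):
        """Unrounded (numerator, denominator, missed-id set) for a scope."""
        index = IndexMonth.coerce(index)
        drugs = tuple(drugs)
        if not drugs:
            raise ConfigurationError("drug set must not be empty")
        requirements = {}
        for drug in drugs:
            req = _required_tests(drug, tests)
            if req:
                requirements[drug] = req
        if not requirements:
            raise ConfigurationError(
                f"no drug in {drugs} requires any of the requested tests"
            )
        den_sets, cov = self._scan(index)
        num = den = 0
        missed_ids: set = set()
        for drug, req in requirements.items():
            d = den_sets[drug]
            if restrict_ids is not None:
                d = d & restrict_ids
            covered = d
            for t in req:
                covered = covered & cov[t]
            den += len(d)
            num += len(d) - len(covered)
            missed_ids |= d - covered
        return num, den, missed_ids

    def indicator(
        self, index, drugs=DRUGS, tests=None, group=None, category=None
    ) -> MonthlyIndicatorResult:
        index = IndexMonth.coerce(index)
        restrict = None
        if group is not None:
            restrict = self.subgroup_ids(group, category)
        num, den, _ = self.raw_counts(index, drugs, tests, restrict)
        num_r, den_r = round5(num), round5(den)
        return MonthlyIndicatorResult(
            month=index,
            drugs=tuple(drugs),
            tests=None if tests is None else tuple(sorted(tests)),
            group=group,
            category=category,
            numerator_rounded=num_r,
            denominator_rounded=den_r,
            percentage=aggregate_percentage(num_r, den_r),
            numerator_raw=num,
            denominator_raw=den,
        )

    def subgroup_ids(self, group: str, category) -> set:
        if group not in SUBGROUP_COLUMNS and group != "practice_id":
            raise ConfigurationError(f"unknown subgroup column {group!r}")
        col = self.data.patients[group]
        if pd.isna(category) or category == "missing":
            if group in ("ethnicity", "region"):
                mask = col.isna() | (col == "missing")
            else:
                mask = col.isna()
        else:
            mask = col == category
        return set(self.data.patients.loc[mask, "patient_id"])

    def series(
        self, start, end, drugs=DRUGS, tests=None, group=None, category=None
    ) -> list[MonthlyIndicatorResult]:
        return [
            self.indicator(m, drugs, tests, group, category)
            for m in month_range(start, end)
        ]

    def cumulative(self, start, end, drugs=DRUGS, tests=None) -> CumulativeTotals:
        total = den_total = 0
        unique: set = set()
        for m in month_range(start, end):
            num, den, missed = self.raw_counts(m, drugs, tests)
            total += num
            den_total += den
            unique |= missed
        return CumulativeTotals(
            total_events=total,
            total_denominator_events=den_total,
            unique_patients=len(unique),
        )

    def any_denominator_ids(self, index) -> set:
        """Patients in at least one drug's denominator at ``index``."""
        den, _ = self._scan(IndexMonth.coerce(index))
        out: set = set()
        for ids in den.values():
            out |= ids
        return out


# ---------------------------------------------------------------------------
# module-level convenience wrappers


def monthly_indicator(data, index, drugs=DRUGS, tests=None, group=None,
                      category=None) -> MonthlyIndicatorResult:
    return IndicatorEngine(data).indicator(index, drugs, tests, group, category)


def monthly_series(data, start, end, drugs=DRUGS, tests=None, group=None,
                   category=None) -> list[MonthlyIndicatorResult]:
    return IndicatorEngine(data).series(start, end, drugs, tests, group, category)


def cumulative_totals(data, start, end, drugs=DRUGS, tests=None) -> CumulativeTotals:
    return IndicatorEngine(data).cumulative(start, end, drugs, tests)


def series_to_frame(results) -> pd.DataFrame:
    """Tidy frame of a monthly series (reportable rounded counts only)."""
    rows = []
    for r in results:
        rows.append(
            {
                "month": str(r.month),
                "drugs": "+".join(r.drugs),
                "tests": "" if r.tests is None else "+".join(r.tests),
                "group": "" if r.group is None else r.group,
                "category": "" if r.category is None else str(r.category),
                "numerator": r.numerator_rounded,
                "denominator": r.denominator_rounded,
                "percentage": r.percentage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "month", "drugs", "tests", "group", "category",
            "numerator", "denominator", "percentage",
        ],
    )


#: Fixed category order per subgroup for reporting.
CATEGORY_ORDER: dict[str, list] = {
    "age_band": ["18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"],
    "sex": ["female", "male"],
    "ethnicity": ["Black", "Mixed", "Other", "South Asian", "White", "missing"],
    "region": [
        "East", "East Midlands", "London", "North East", "North West",
        "South East", "South West", "West Midlands",
        "Yorkshire and The Humber", "missing",
    ],
    "imd_quintile": [1, 2, 3, 4, 5],
    "rural_urban": [1, 2, 3, 4, 5, 6, 7, 8],
    "care_home": [True, False],
    "dementia": [True, False],
    "housebound": [True, False],
    "learning_disability": [True, False],
    "serious_mental_illness": [True, False],
}


def cohort_summary(data, index, drugs=DRUGS) -> pd.DataFrame:
    """Cohort description at one month: rounded counts and percentages.

    Patients included in at least one drug's denominator, broken down by
    every subgroup.  Counts are rounded to the nearest 5 and percentages
    taken as a proportion of the rounded subgroup total, so each group's
    percentages sum to ~100 regardless of rounding.
    """
    engine = IndicatorEngine(data)
    ids = engine.any_denominator_ids(index)
    pats = data.patients[data.patients["patient_id"].isin(ids)]
    rows = [
        {
            "group": "population",
            "category": "total",
            "count": round5(len(pats)),
            "percentage": 100.0 if len(pats) else math.nan,
        }
    ]
    for group, categories in CATEGORY_ORDER.items():
        col = pats[group]
        counts = []
        for cat in categories:
            if cat == "missing" and group in ("ethnicity", "region"):
                n = int((col.isna() | (col == "missing")).sum())
            else:
                n = int((col == cat).sum())
            counts.append(round5(n))
        total = sum(counts)
        for cat, n in zip(categories, counts):
            pct = aggregate_percentage(n, total) if total else math.nan
            label = {True: "yes", False: "no"}.get(cat, cat)
            rows.append(
                {"group": group, "category": str(label), "count": n,
                 "percentage": pct}
            )
    return pd.DataFrame(rows, columns=["group", "category", "count", "percentage"])
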