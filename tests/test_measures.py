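"""Indicator arithmetic, rounding, series semantics and cumulative totals."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmard_monitor import (
    ConfigurationError,
    IndicatorEngine,
    aggregate_percentage,
    cohort_summary,
    cumulative_totals,
    missed_for_drug,
    monthly_indicator,
    monthly_series,
    pp_change,
    round5,
)

from conftest import build_data, make_patient, quarterly_issues
from reference import brute_force_counts

MONTH = "2020-05"


class TestRound5:
    @pytest.mark.parametrize("raw, expected", [(12, 10), (13, 15), (0, 0),
                                               (2, 0), (3, 5), (97, 95),
                                               (98, 100)])
    def test_examples(self, raw, expected):
        assert round5(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            round5(-1)

    @given(st.integers(min_value=0, max_value=10_000_000))
    @settings(max_examples=200, deadline=None)
    def test_nearest_multiple_property(self, n):
        r = round5(n)
        assert r % 5 == 0
        assert abs(r - n) <= 2


class TestPercentages:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (977_354, 3_146_849, 31.1),
            (125_850, 193_665, 65.0),
            (517_770, 2_106_050, 24.6),
            (111_215, 193_665, 57.4),
            (793_870, 3_146_849, 25.2),
            (820_895, 3_146_849, 26.1),
            (810_255, 3_146_849, 25.7),
            (57_620, 94_610, 60.9),
            (0, 100, 0.0),
            (1, 16, 6.3),  # half-up, not banker's rounding
        ],
    )
    def test_aggregate_percentage(self, num, den, expected):
        assert aggregate_percentage(num, den) == expected

    def test_zero_denominator_is_undefined_not_a_crash(self):
        assert math.isnan(aggregate_percentage(5, 0))

    @pytest.mark.parametrize(
        "a, b, expected",
        [(28.4, 40.8, 12.4), (40.8, 28.1, -12.7), (33.3, 33.3, 0.0)],
    )
    def test_pp_change(self, a, b, expected):
        assert pp_change(a, b) == expected


class TestMissedForDrug:
    def test_leflunomide_without_bp_is_missed(self):
        tests = [("FBC", "2020-04-01"), ("LFT", "2020-04-01"),
                 ("UE", "2020-04-01")]
        assert missed_for_drug(tests, "leflunomide", MONTH) is True
        assert missed_for_drug(tests, "methotrexate", MONTH) is False

    def test_tests_on_index_date_count(self):
        tests = [(t, "2020-05-31") for t in ("FBC", "LFT", "UE")]
        assert missed_for_drug(tests, "methotrexate", MONTH) is False

    def test_tests_on_lookback_start_count(self):
        tests = [(t, "2020-03-01") for t in ("FBC", "LFT", "UE")]
        assert missed_for_drug(tests, "methotrexate", MONTH) is False

    def test_tests_before_lookback_do_not_count(self):
        tests = [(t, "2020-02-29") for t in ("FBC", "LFT", "UE")]
        assert missed_for_drug(tests, "methotrexate", MONTH) is True

    def test_no_tests_is_missed(self):
        assert missed_for_drug([], "azathioprine", MONTH) is True

    def test_irrelevant_test_type_ignored(self):
        """BP never affects a drug that does not require it."""
        tests = [(t, "2020-04-01") for t in ("FBC", "LFT", "UE", "BP")]
        only_bloods = [(t, "2020-04-01") for t in ("FBC", "LFT", "UE")]
        assert missed_for_drug(tests, "azathioprine", MONTH) is missed_for_drug(
            only_bloods, "azathioprine", MONTH
        )


def _fixture_13_pairs():
    """13 patient-drug pairs, 7 of them missing monitoring in May 2020."""
    patients = [make_patient(f"p{i:02d}") for i in range(12)]
    rx = []
    for i in range(12):
        rx += quarterly_issues(f"p{i:02d}", "methotrexate", "2019-12-15", 3)
    # p00 is also on azathioprine -> 13 pairs in total
    rx += quarterly_issues("p00", "azathioprine", "2019-12-20", 3)
    tests = []
    # p00..p04 fully monitored (p00's one panel covers both its drugs),
    # giving 6 covered pairs; p05/p06 have incomplete panels and p07..p11
    # nothing, giving 7 missed pairs.
    for i in range(5):
        tests += [(f"p{i:02d}", t, "2020-04-10") for t in ("FBC", "LFT", "UE")]
    tests += [("p05", "FBC", "2020-04-10"), ("p05", "LFT", "2020-04-10")]
    tests += [("p06", "FBC", "2020-04-10"), ("p06", "LFT", "2020-04-10")]
    return build_data(patients, rx, tests)


class TestMonthlyIndicator:
    def test_rounding_of_thirteen_pair_fixture(self):
        data = _fixture_13_pairs()
        num, den = 0, 0
        for drug in ("azathioprine", "leflunomide", "methotrexate"):
            n, d = brute_force_counts(data, 2020, 5, [drug])
            num += n
            den += d
        assert (num, den) == (7, 13)
        result = monthly_indicator(data, MONTH)
        assert result.numerator_raw == 7
        assert result.denominator_raw == 13
        assert result.numerator_rounded == 5
        assert result.denominator_rounded == 15
        assert result.percentage == 33.3

    def test_empty_drug_set_rejected(self):
        with pytest.raises(ConfigurationError):
            monthly_indicator(_fixture_13_pairs(), MONTH, drugs=())

    def test_bp_indicator_needs_a_bp_drug(self):
        with pytest.raises(ConfigurationError):
            monthly_indicator(
                _fixture_13_pairs(), MONTH, drugs=("azathioprine",),
                tests={"BP"},
            )

    def test_fully_monitored_population_scores_zero(self):
        patients = [make_patient(f"p{i}") for i in range(4)]
        rx, tests = [], []
        for i in range(4):
            rx += quarterly_issues(f"p{i}", "methotrexate", "2019-12-15", 3)
            tests += [(f"p{i}", t, "2020-05-01") for t in ("FBC", "LFT", "UE")]
        result = monthly_indicator(build_data(patients, rx, tests), MONTH)
        assert result.percentage == 0.0

    def test_subgroup_restriction(self):
        patients = [make_patient("a", sex="female"), make_patient("b", sex="male")]
        rx = quarterly_issues("a", "methotrexate", "2019-12-15", 3)
        rx += quarterly_issues("b", "methotrexate", "2019-12-15", 3)
        data = build_data(patients, rx, [])
        r = monthly_indicator(data, MONTH, group="sex", category="female")
        assert r.denominator_raw == 1

    def test_overall_equals_sum_of_per_drug_counts(self, small_sim):
        engine = IndicatorEngine(small_sim)
        overall = engine.indicator("2020-05")
        parts = [
            engine.indicator("2020-05", drugs=(d,))
            for d in ("azathioprine", "leflunomide", "methotrexate")
        ]
        assert overall.denominator_raw == sum(p.denominator_raw for p in parts)
        assert overall.numerator_raw == sum(p.numerator_raw for p in parts)

    def test_per_test_numerator_bounded_by_all_tests(self, small_sim):
        engine = IndicatorEngine(small_sim)
        full = engine.indicator("2020-05", drugs=("leflunomide",))
        for t in ("FBC", "LFT", "UE", "BP"):
            sub = engine.indicator("2020-05", drugs=("leflunomide",), tests={t})
            assert sub.numerator_raw <= full.numerator_raw
            assert sub.denominator_raw == full.denominator_raw

    def test_rounding_perturbs_percentage_within_bound(self, small_sim):
        engine = IndicatorEngine(small_sim)
        r = engine.indicator("2020-05")
        raw_pct = 100 * r.numerator_raw / r.denominator_raw
        bound = 100 * (
            2.5 / r.denominator_raw
            + 2.5 * r.numerator_raw / r.denominator_raw**2
        )
        assert abs(r.percentage - raw_pct) <= bound + 0.05  # 1dp display rounding


class TestMonthlySeries:
    def test_single_month_range(self):
        data = _fixture_13_pairs()
        series = monthly_series(data, MONTH, MONTH)
        assert len(series) == 1
        assert series[0] == monthly_indicator(data, MONTH)

    def test_translation_equivariance(self):
        """Shifting all events one month forward shifts the series."""
        data = _fixture_13_pairs()
        shifted = build_data(
            data.patients.to_dict("records"),
            [
                (r["patient_id"], r["drug"], r["issue_date"] + pd.DateOffset(months=1))
                for r in data.prescriptions.to_dict("records")
            ],
            [
                (r["patient_id"], r["test_type"], r["date"] + pd.DateOffset(months=1))
                for r in data.tests.to_dict("records")
            ],
        )
        original = monthly_series(data, "2020-03", "2020-07")
        moved = monthly_series(shifted, "2020-04", "2020-08")
        for a, b in zip(original, moved):
            assert (a.numerator_raw, a.denominator_raw) == (
                b.numerator_raw, b.denominator_raw
            )

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            monthly_series(_fixture_13_pairs(), "2020-06", "2020-05")


class TestCumulativeTotals:
    def test_three_consecutive_missed_months(self):
        patients = [make_patient("p1")]
        rx = quarterly_issues("p1", "methotrexate", "2019-12-15", 4)
        data = build_data(patients, rx, [])
        totals = cumulative_totals(data, "2020-04", "2020-06")
        assert totals.total_events == 3
        assert totals.unique_patients == 1
        assert totals.repeat_ratio == 3.0

    def test_no_missed_events_has_undefined_ratio(self):
        patients = [make_patient("p1")]
        rx = quarterly_issues("p1", "methotrexate", "2019-12-15", 4)
        tests = [("p1", t, d) for t in ("FBC", "LFT", "UE")
                 for d in ("2020-02-15", "2020-05-15")]
        totals = cumulative_totals(build_data(patients, rx, tests),
                                   "2020-04", "2020-06")
        assert totals.total_events == 0
        assert math.isnan(totals.repeat_ratio)

    def test_five_patient_enumeration(self):
        patients = [make_patient(f"p{i}") for i in range(5)]
        rx, tests = [], []
        for i in range(5):
            rx += quarterly_issues(f"p{i}", "methotrexate", "2019-12-15", 4)
        # p0, p1 monitored in April only; p2 monitored both months;
        # p3, p4 never monitored
        for pid in ("p0", "p1", "p2"):
            tests += [(pid, t, "2020-04-10") for t in ("FBC", "LFT", "UE")]
        tests += [("p2", t, "2020-06-20") for t in ("FBC", "LFT", "UE")]
        data = build_data(patients, rx, tests)
        expected_events = 0
        for y, m in ((2020, 4), (2020, 5), (2020, 6)):
            n, _ = brute_force_counts(data, y, m, ["methotrexate"])
            expected_events += n
        totals = cumulative_totals(data, "2020-04", "2020-06")
        assert totals.total_events == expected_events
        assert totals.unique_patients == 2  # only p3, p4 ever miss
        assert totals.repeat_ratio == expected_events / 2


class TestCohortSummary:
    def test_sex_percentages_from_rounded_totals(self):
        patients = [make_patient(f"f{i}", sex="female") for i in range(9)]
        patients += [make_patient(f"m{i}", sex="male") for i in range(4)]
        rx = []
        for p in patients:
            rx += quarterly_issues(p["patient_id"], "methotrexate",
                                   "2019-12-15", 3)
        summary = cohort_summary(build_data(patients, rx, []), MONTH)
        sex = summary[summary["group"] == "sex"].set_index("category")
        assert sex.loc["female", "count"] == 10
        assert sex.loc["male", "count"] == 5
        assert sex.loc["female", "percentage"] == 66.7

    def test_zero_count_categories_retained(self):
        patients = [make_patient("p1", ethnicity="White")]
        rx = quarterly_issues("p1", "methotrexate", "2019-12-15", 3)
        summary = cohort_summary(build_data(patients, rx, []), MONTH)
        eth = summary[summary["group"] == "ethnicity"]
        assert set(eth["category"]) == {
            "Black", "Mixed", "Other", "South Asian", "White", "missing"
        }
        assert (eth.set_index("category")["count"]["Black"]) == 0

    def test_single_category_group_is_total(self):
        patients = [make_patient(f"p{i}", sex="female") for i in range(3)]
        rx = []
        for p in patients:
            rx += quarterly_issues(p["patient_id"], "methotrexate",
                                   "2019-12-15", 3)
        summary = cohort_summary(build_data(patients, rx, []), MONTH)
        sex = summary[summary["group"] == "sex"].set_index("category")
        assert sex.loc["female", "percentage"] == 100.0


class TestOracleEquivalence:
    def test_engine_matches_bruteforce_on_simulated_cohort(self, small_sim):
        for month in ("2020-02", "2020-05", "2021-08"):
            y, m = (int(x) for x in month.split("-"))
            for drugs in (["methotrexate"], ["azathioprine", "leflunomide",
                                             "methotrexate"]):
                expected = brute_force_counts(small_sim, y, m, drugs)
                r = monthly_indicator(small_sim, month, drugs=tuple(drugs))
                assert (r.numerator_raw, r.denominator_raw) == expected
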