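"""Practice-level variation and inferential statistics.

Three tools describe how the missed-monitoring indicator varies:

* practice-level rates summarised as deciles per month (the standard
  decile chart for quality-indicator variation across GP practices);
* a two-proportion z-test (pooled variance) for the change in the
  aggregate rate between two named periods;
* Cochran's Q to test whether the baseline-to-disruption change is
  heterogeneous across the categories of a subgroup, weighting each
  category's change by the inverse of its sampling variance.

Q is computed on the proportion scale: for category i with baseline and
comparison proportions (p1, p2) and denominators (n1, n2),

    d_i = p2 - p1,      v_i = p1(1-p1)/n1 + p2(1-p2)/n2,
    w_i = 1/v_i,        Q = sum_i w_i (d_i - dbar)^2,

with dbar the w-weighted mean and Q ~ chi-square(k-1) under homogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IndexMonth, month_range
from .config import DRUGS
from .errors import DataError, InsufficientDataError
from .measures import (
    CATEGORY_ORDER,
    IndicatorEngine,
    aggregate_percentage,
    round5,
)

DECILE_PROBS = tuple(range(10, 100, 10))


# ---------------------------------------------------------------------------
# practice deciles


def practice_rates(data, index, drugs=DRUGS, tests=None, engine=None) -> dict:
    """Per-practice indicator percentages at one month.

    Each practice's numerator and denominator are rounded to the nearest
    5 (as for every reported granularity); practices whose rounded
    denominator is 0 are excluded.
    """
    engine = engine or IndicatorEngine(data)
    index = IndexMonth.coerce(index)
    by_practice = data.patients.groupby("practice_id")["patient_id"]
    rates = {}
    for practice, ids in by_practice:
        num, den, _ = engine.raw_counts(index, drugs, tests, set(ids))
        num_r, den_r = round5(num), round5(den)
        if den_r == 0:
            continue
        rates[practice] = aggregate_percentage(num_r, den_r)
    return rates


def deciles(rates) -> dict:
    """d1..d9 of a collection of rates by linear interpolation."""
    values = np.asarray(list(rates), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need at least 2 rates for deciles, got {values.size}"
        )
    points = np.percentile(values, DECILE_PROBS, method="linear")
    return {f"d{i}": float(p) for i, p in zip(range(1, 10), points)}


def practice_decile_series(data, start, end, drugs=DRUGS, tests=None) -> pd.DataFrame:
    """Monthly decile summary of practice-level rates."""
    engine = IndicatorEngine(data)
    rows = []
    for m in month_range(start, end):
        rates = practice_rates(data, m, drugs, tests, engine=engine)
        if len(rates) < 2:
            continue
        d = deciles(rates.values())
        d["month"] = str(m)
        d["median"] = d["d5"]
        d["interdecile_range"] = d["d9"] - d["d1"]
        d["n_practices"] = len(rates)
        rows.append(d)
    cols = ["month"] + [f"d{i}" for i in range(1, 10)] + [
        "median", "interdecile_range", "n_practices"
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# change test


@dataclass(frozen=True)
class ChangeTestResult:
    """Two-proportion z-test of a change between two periods.

    ``estimate`` is the percentage-point difference (period 2 minus
    period 1) with a Wald 95% interval.
    """

    statistic: float
    p_value: float
    estimate: float
    ci_low: float
    ci_high: float


def change_test(n1: int, x1: int, n2: int, x2: int) -> ChangeTestResult:
    """Pooled-variance two-proportion z-test on aggregate counts."""
    if n1 <= 0 or n2 <= 0:
        raise InsufficientDataError("both periods need a positive denominator")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("numerators must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p2 - p1) / se
    p_value = 2 * stats.norm.sf(abs(z))
    se_wald = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    diff = 100 * (p2 - p1)
    half = 100 * 1.959963984540054 * se_wald
    return ChangeTestResult(
        statistic=float(z),
        p_value=float(p_value),
        estimate=float(diff),
        ci_low=float(diff - half),
        ci_high=float(diff + half),
    )


def practice_change_test(rates1, rates2) -> ChangeTestResult:
    """Welch two-sample t-test on practice-level rates (non-default option).

    An alternative reading of the period-change test that compares the
    distribution of practice-level percentages between two months rather
    than the pooled population proportions.
    """
    a = np.asarray(list(rates1), dtype=float)
    b = np.asarray(list(rates2), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least 2 practices per period")
    t, p = stats.ttest_ind(b, a, equal_var=False)
    diff = float(b.mean() - a.mean())
    se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    half = 1.959963984540054 * se
    return ChangeTestResult(
        statistic=float(t), p_value=float(p),
        estimate=diff, ci_low=diff - half, ci_high=diff + half,
    )


# ---------------------------------------------------------------------------
# Cochran's Q


@dataclass(frozen=True)
class SubgroupDelta:
    """One category's baseline/comparison rates and their change."""

    group: str
    category: object
    p1: float
    p2: float
    n1: int
    n2: int

    @property
    def delta(self) -> float:
        """Change in percentage points (comparison minus baseline)."""
        return 100.0 * (self.p2 - self.p1)

    @property
    def variance(self) -> float:
        """Sampling variance of p2 - p1 on the proportion scale.

        Proportions are clamped to [0.5/n, 1 - 0.5/n] so that degenerate
        categories (0% or 100%) keep a positive variance.
        """
        v = 0.0
        for p, n in ((self.p1, self.n1), (self.p2, self.n2)):
            if n <= 0:
                raise DataError(
                    f"non-positive denominator for {self.group}/{self.category}"
                )
            p = min(max(p, 0.5 / n), 1 - 0.5 / n)
            v += p * (1 - p) / n
        return v


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail p-value."""

    Q: float
    df: int
    p_value: float


def cochran_q_from_arrays(effects, variances) -> HeterogeneityResult:
    """Cochran's Q for arbitrary effect estimates with known variances."""
    d = np.asarray(list(effects), dtype=float)
    v = np.asarray(list(variances), dtype=float)
    if d.size < 2:
        raise InsufficientDataError(
            f"need at least 2 categories for Cochran's Q, got {d.size}"
        )
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DataError("all variances must be positive and finite")
    w = 1.0 / v
    dbar = np.sum(w * d) / np.sum(w)
    q = float(np.sum(w * (d - dbar) ** 2))
    df = int(d.size - 1)
    return HeterogeneityResult(Q=q, df=df, p_value=float(stats.chi2.sf(q, df)))


def cochran_q(deltas) -> HeterogeneityResult:
    """Cochran's Q across a family of :class:`SubgroupDelta`.

    Changes enter on the proportion scale (``delta``/100), matching the
    scale of their sampling variances.
    """
    deltas = list(deltas)
    return cochran_q_from_arrays(
        [d.p2 - d.p1 for d in deltas], [d.variance for d in deltas]
    )


def subgroup_deltas(
    data, group, baseline, comparison, drugs=DRUGS, tests=None, engine=None
) -> list[SubgroupDelta]:
    """Per-category baseline/comparison rates from rounded counts.

    Categories with a zero rounded denominator in either period are
    dropped (they carry no reportable rate).
    """
    engine = engine or IndicatorEngine(data)
    out = []
    for category in CATEGORY_ORDER.get(group, []):
        r1 = engine.indicator(baseline, drugs, tests, group, category)
        r2 = engine.indicator(comparison, drugs, tests, group, category)
        if r1.denominator_rounded == 0 or r2.denominator_rounded == 0:
            continue
        out.append(
            SubgroupDelta(
                group=group,
                category=category,
                p1=r1.numerator_rounded / r1.denominator_rounded,
                p2=r2.numerator_rounded / r2.denominator_rounded,
                n1=r1.denominator_rounded,
                n2=r2.denominator_rounded,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of Q


def simulate_q(
    n_per_category, p_baseline, p_comparison, n_reps: int, rng, k: int | None = None
) -> np.ndarray:
    """Q statistics from binomial sampling of per-category period rates.

    ``n_per_category``, ``p_baseline`` and ``p_comparison`` are scalars or
    length-k arrays (``k`` may be given explicitly when all are scalar);
    a common change across the k categories gives the null of
    homogeneity.  Returns ``n_reps`` Q values.
    """
    n = np.atleast_1d(np.asarray(n_per_category, dtype=int))
    p1 = np.atleast_1d(np.asarray(p_baseline, dtype=float))
    p2 = np.atleast_1d(np.asarray(p_comparison, dtype=float))
    if k is None:
        k = max(n.size, p1.size, p2.size)
    n = np.broadcast_to(n, (k,))
    p1 = np.broadcast_to(p1, (k,))
    p2 = np.broadcast_to(p2, (k,))
    if k < 2:
        raise InsufficientDataError("need at least 2 categories")
    x1 = rng.binomial(n, p1, size=(n_reps, k))
    x2 = rng.binomial(n, p2, size=(n_reps, k))
    ph1, ph2 = x1 / n, x2 / n
    lo = 0.5 / n
    ph1c = np.clip(ph1, lo, 1 - lo)
    ph2c = np.clip(ph2, lo, 1 - lo)
    v = ph1c * (1 - ph1c) / n + ph2c * (1 - ph2c) / n
    d = ph2 - ph1
    w = 1.0 / v
    dbar = (w * d).sum(axis=1, keepdims=True) / w.sum(axis=1, keepdims=True)
    return ((w * (d - dbar) ** 2).sum(axis=1))


def q_rejection_rate(q_values, df: int, alpha: float = 0.05) -> float:
    """Fraction of Q statistics exceeding the chi-square critical value."""
    crit = stats.chi2.ppf(1 - alpha, df)
    return float(np.mean(np.asarray(q_values) > crit))
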