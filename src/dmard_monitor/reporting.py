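"""Plots and summary tables built from the measures outputs.

Time-series plots mark the baseline and lockdown-analogue months with
dashed vertical reference lines; the decile chart shows the practice
distribution (dashed deciles, solid median).  The comparison table pairs
each subgroup category's baseline/lockdown/recovery rates with the
two-proportion change test, and each subgroup family with its Cochran's Q.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import IndexMonth
from .errors import DataError, InsufficientDataError
from .variation import (
    SubgroupDelta,
    change_test,
    cochran_q,
)

#: Default named periods: 3-month windows ending at these months.
DEFAULT_BASELINE = "2020-02"
DEFAULT_LOCKDOWN = "2020-05"
DEFAULT_RECOVERY = "2022-07"


def _month_axis(frame: pd.DataFrame) -> pd.Series:
    return pd.PeriodIndex(frame["month"], freq="M").to_timestamp()


def _reference_lines(ax, baseline: str, lockdown: str):
    for month, colour, label in (
        (baseline, "tab:orange", "baseline"),
        (lockdown, "tab:green", "lockdown window"),
    ):
        ts = pd.Period(month, freq="M").to_timestamp()
        ax.axvline(ts, linestyle="--", color=colour, label=label)


def plot_indicator_series(
    frame: pd.DataFrame,
    path,
    title: str,
    baseline: str = DEFAULT_BASELINE,
    lockdown: str = DEFAULT_LOCKDOWN,
) -> Path:
    """Line chart of one monthly indicator CSV (optionally per category)."""
    fig, ax = plt.subplots(figsize=(9, 5))
    if frame["category"].replace("", pd.NA).notna().any():
        for cat, sub in frame.groupby("category"):
            ax.plot(_month_axis(sub), sub["percentage"], label=str(cat))
        ax.legend(fontsize=8, ncol=2)
    else:
        ax.plot(_month_axis(frame), frame["percentage"], color="tab:blue")
    _reference_lines(ax, baseline, lockdown)
    ax.set_ylabel("% of denominator with missed monitoring")
    ax.set_xlabel("month")
    ax.set_ylim(bottom=0)
    ax.set_title(title)
    fig.autofmt_xdate()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_decile_chart(
    decile_frame: pd.DataFrame,
    path,
    baseline: str = DEFAULT_BASELINE,
    lockdown: str = DEFAULT_LOCKDOWN,
) -> Path:
    """Practice-level decile chart (median solid, other deciles dashed)."""
    fig, ax = plt.subplots(figsize=(9, 5))
    months = _month_axis(decile_frame)
    for i in range(1, 10):
        style = "-" if i == 5 else "--"
        width = 1.8 if i == 5 else 0.8
        ax.plot(months, decile_frame[f"d{i}"], style, color="tab:blue",
                linewidth=width)
    _reference_lines(ax, baseline, lockdown)
    ax.set_ylabel("% missed monitoring (practice deciles)")
    ax.set_xlabel("month")
    ax.set_ylim(0, 100)
    ax.set_title("Practice-level variation in missed monitoring")
    fig.autofmt_xdate()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def comparison_table(
    group_frames: dict[str, pd.DataFrame],
    baseline: str = DEFAULT_BASELINE,
    lockdown: str = DEFAULT_LOCKDOWN,
    recovery: str = DEFAULT_RECOVERY,
) -> pd.DataFrame:
    """Baseline/lockdown/recovery rates with change tests and Q per group.

    ``group_frames`` maps a subgroup column name to its monthly indicator
    frame (one row per month x category, rounded counts).
    """
    for m in (baseline, lockdown, recovery):
        IndexMonth.from_string(m)
    rows = []
    for group, frame in group_frames.items():
        per_cat = {}
        for cat, sub in frame.groupby("category", sort=False):
            sub = sub.set_index("month")
            per_cat[cat] = sub
        deltas = []
        cat_rows = []
        for cat, sub in per_cat.items():
            try:
                b = sub.loc[baseline]
                l = sub.loc[lockdown]
                r = sub.loc[recovery] if recovery in sub.index else None
            except KeyError:
                continue
            if b["denominator"] == 0 or l["denominator"] == 0:
                continue
            test = change_test(
                int(b["denominator"]), int(b["numerator"]),
                int(l["denominator"]), int(l["numerator"]),
            )
            deltas.append(
                SubgroupDelta(
                    group=group, category=cat,
                    p1=b["numerator"] / b["denominator"],
                    p2=l["numerator"] / l["denominator"],
                    n1=int(b["denominator"]), n2=int(l["denominator"]),
                )
            )
            cat_rows.append(
                {
                    "group": group,
                    "category": cat,
                    "baseline_pct": b["percentage"],
                    "lockdown_pct": l["percentage"],
                    "recovery_pct": None if r is None else r["percentage"],
                    "change_pp": test.estimate,
                    "change_ci_low": test.ci_low,
                    "change_ci_high": test.ci_high,
                    "change_z": test.statistic,
                    "change_p": test.p_value,
                }
            )
        if not cat_rows:
            continue
        try:
            het = cochran_q(deltas)
            q, df, qp = het.Q, het.df, het.p_value
        except InsufficientDataError:
            q = df = qp = None
        for row in cat_rows:
            row.update({"q": q, "q_df": df, "q_p": qp})
            rows.append(row)
    if not rows:
        raise DataError("no subgroup series cover the requested periods")
    return pd.DataFrame(rows)
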