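"""Seeded synthetic primary-care EHR generator.

Emulates a prevalent cohort of patients on long-term DMARD repeat
prescribing.  Each on-drug patient receives prescription issues roughly
every 12 weeks (84 +/- 7 days by default) from a staggered start near the
study start, until discontinuation, death or the study end.  Monitoring
due windows are anchored at the first prescription and repeat every
91 days; at each due date the patient attends with probability
``1 - pi``, where

    pi = expit(baseline_miss_logit + practice effect + subgroup offsets
               + patient frailty + shock(t)).

On attendance one event is recorded per required blood test (FBC, LFT,
U&E) sharing a single date, since the panels are drawn together; the
blood-pressure check (leflunomide only) gets an independent draw with an
extra miss offset, reflecting that physical checks are forgone more
readily than blood panels.  ``shock(t)`` equals ``lockdown_shock_logit``
between ``shock_start`` and ``shock_end`` and decays linearly (on the
logit scale) to zero by ``recovery_end``, reproducing an acute service
disruption with rapid recovery.

All randomness flows from ``config.seed`` through independent
sub-streams per stage, so the population and prescribing are unchanged
when only the miss-mechanism parameters vary (common random numbers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import BLOOD_TESTS
from .config import DRUGS, SimulationConfig
from .data import (
    MonitoringData,
    PATIENT_COLUMNS,
    PRESCRIPTION_COLUMNS,
    TEST_COLUMNS,
)

#: Spacing of monitoring due windows (13 weeks), independent of the
#: prescribing interval so that calendar alignment is not artificial.
DUE_INTERVAL_DAYS = 91

_POP, _RX, _TESTS = 0, 1, 2


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stage,))
    )


def _day_number(d) -> int:
    return np.datetime64(d, "D").astype(int)


# ---------------------------------------------------------------------------


def generate_population(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """One row per patient: demographics, flags, practice and dates."""
    config.validate()
    rng = rng or _stage_rng(config, _POP)
    n = config.n_patients
    out = pd.DataFrame(
        {
            "patient_id": [f"p{i:06d}" for i in range(n)],
            "practice_id": [
                f"gp{i:04d}" for i in rng.integers(0, config.n_practices, n)
            ],
        }
    )
    for group, dist in config.demographic_distributions.items():
        cats = list(dist.keys())
        probs = np.asarray([dist[c] for c in cats], dtype=float)
        draws = rng.choice(len(cats), size=n, p=probs / probs.sum())
        out[group] = [cats[i] for i in draws]
    start = np.datetime64(config.study_start, "D")
    end = np.datetime64(config.study_end, "D")
    # Registration predates the study by 6 months to 20 years (no churn).
    out["registration_start"] = pd.to_datetime(
        start - rng.integers(183, 7300, n).astype("timedelta64[D]")
    )
    span_days = int((end - start).astype(int)) + 1
    years = span_days / 365.25
    p_death = 1.0 - np.exp(-config.annual_death_rate * years)
    died = rng.random(n) < p_death
    death_days = rng.integers(0, span_days, n)
    death = pd.Series(pd.NaT, index=out.index, dtype="datetime64[ns]")
    death[died] = pd.to_datetime(
        start + death_days[died].astype("timedelta64[D]")
    )
    out["death_date"] = death
    if config.missing_core_fraction > 0:
        m = int(round(config.missing_core_fraction * n))
        victims = rng.choice(n, size=m, replace=False)
        fields = ("age_band", "sex", "imd_quintile", "rural_urban")
        which = rng.integers(0, len(fields), m)
        for row, f_idx in zip(victims, which):
            out.loc[row, fields[f_idx]] = None
    out["imd_quintile"] = out["imd_quintile"].astype("Int64")
    out["rural_urban"] = out["rural_urban"].astype("Int64")
    return out[PATIENT_COLUMNS]


# ---------------------------------------------------------------------------


def _assign_drugs(patients: pd.DataFrame, config: SimulationConfig, rng):
    """(patient_row_index, drug) pairs: primary draw + rare second drug."""
    n = len(patients)
    drugs = [d for d in DRUGS if config.drug_prevalence.get(d, 0.0) > 0]
    probs = np.asarray([config.drug_prevalence[d] for d in drugs], dtype=float)
    p_none = max(0.0, 1.0 - probs.sum())
    choices = drugs + [None]
    draw = rng.choice(
        len(choices), size=n, p=np.append(probs, p_none) / (probs.sum() + p_none)
    )
    primary = [choices[i] for i in draw]
    second_roll = rng.random(n)
    pairs: list[tuple[int, str]] = []
    for i, drug in enumerate(primary):
        if drug is None:
            continue
        pairs.append((i, drug))
        if len(drugs) > 1 and second_roll[i] < config.combination_therapy_rate:
            others = [d for d in drugs if d != drug]
            w = np.asarray([config.drug_prevalence[d] for d in others], float)
            j = rng.choice(len(others), p=w / w.sum())
            pairs.append((i, others[j]))
    return pairs


def generate_prescribing(
    patients: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Issue events per patient-drug: staggered start, jittered intervals."""
    config.validate()
    rng = rng or _stage_rng(config, _RX)
    pairs = _assign_drugs(patients, config, rng)
    n_rows = len(pairs)
    start_ord = _day_number(config.study_start)
    end_ord = _day_number(config.study_end)
    death_ord = np.full(len(patients), np.iinfo(np.int64).max)
    has_death = patients["death_date"].notna().to_numpy()
    death_ord[has_death] = (
        patients.loc[has_death, "death_date"]
        .to_numpy()
        .astype("datetime64[D]")
        .astype(int)
    )
    if n_rows == 0:
        return pd.DataFrame(columns=PRESCRIPTION_COLUMNS)

    interval = config.prescription_interval_days
    sd = config.prescription_interval_sd
    first = start_ord + rng.integers(0, interval, n_rows)
    if config.discontinuation_hazard > 0:
        max_issues = rng.geometric(config.discontinuation_hazard, n_rows)
    else:
        max_issues = np.full(n_rows, np.iinfo(np.int64).max)

    span = end_ord - start_ord + 1
    lower_gap = max(interval - 6.0 * sd, 1.0)
    max_k = min(int(np.ceil(span / lower_gap)) + 2, span + 2)
    jitter = np.clip(rng.normal(0.0, 1.0, (n_rows, max_k)) * sd, -6 * sd, 6 * sd)
    gaps = np.maximum(np.rint(interval + jitter), 1.0).astype(np.int64)
    offsets = np.concatenate(
        [np.zeros((n_rows, 1), dtype=np.int64), np.cumsum(gaps, axis=1)[:, :-1]],
        axis=1,
    )
    dates = first[:, None] + offsets
    patient_rows = np.asarray([p for p, _ in pairs])
    horizon = np.minimum(end_ord, death_ord[patient_rows])
    k = np.arange(max_k)[None, :]
    keep = (dates <= horizon[:, None]) & (k < max_issues[:, None])

    row_idx, _ = np.nonzero(keep)
    issue_ord = dates[keep]
    pat_ids = patients["patient_id"].to_numpy()
    frame = pd.DataFrame(
        {
            "patient_id": pat_ids[patient_rows[row_idx]],
            "drug": np.asarray([d for _, d in pairs])[row_idx],
            "issue_date": pd.to_datetime(issue_ord.astype("datetime64[D]")),
        }
    )
    frame = frame.sort_values(PRESCRIPTION_COLUMNS, kind="mergesort")
    return frame.reset_index(drop=True)[PRESCRIPTION_COLUMNS]


# ---------------------------------------------------------------------------


def _shock_logits(due_ord: np.ndarray, config: SimulationConfig) -> np.ndarray:
    s0 = _day_number(config.shock_start)
    s1 = _day_number(config.shock_end)
    r1 = _day_number(config.recovery_end)
    shock = np.zeros(due_ord.shape)
    inside = (due_ord >= s0) & (due_ord <= s1)
    shock[inside] = config.lockdown_shock_logit
    if r1 > s1:
        decay = (due_ord > s1) & (due_ord <= r1)
        shock[decay] = config.lockdown_shock_logit * (r1 - due_ord[decay]) / (r1 - s1)
    return shock


def _patient_logit_offsets(patients: pd.DataFrame, config: SimulationConfig, rng):
    """Practice effect + subgroup offsets + frailty, one value per patient."""
    practices = np.sort(patients["practice_id"].unique())
    effects = rng.normal(0.0, 1.0, len(practices)) * config.practice_effect_sd
    practice_effect = dict(zip(practices, effects))
    offset = patients["practice_id"].map(practice_effect).to_numpy(dtype=float)
    for (group, category), value in config.subgroup_effects.items():
        offset += np.where(patients[group].to_numpy() == category, value, 0.0)
    offset += rng.normal(0.0, 1.0, len(patients)) * config.patient_frailty_sd
    return offset


def generate_tests(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Monitoring test events from the per-due-window miss mechanism."""
    config.validate()
    rng = rng or _stage_rng(config, _TESTS)
    if prescriptions.empty:
        return pd.DataFrame(columns=TEST_COLUMNS)

    offsets = _patient_logit_offsets(patients, config, rng)
    patient_pos = {pid: i for i, pid in enumerate(patients["patient_id"])}

    issue_ord = prescriptions["issue_date"].to_numpy().astype("datetime64[D]").astype(int)
    grouped = (
        pd.DataFrame(
            {
                "patient_id": prescriptions["patient_id"],
                "drug": prescriptions["drug"],
                "ord": issue_ord,
            }
        )
        .groupby(["patient_id", "drug"], sort=True)["ord"]
        .agg(["min", "max"])
        .reset_index()
    )
    end_ord = _day_number(config.study_end)
    pos = grouped["patient_id"].map(patient_pos).to_numpy()
    death_d = patients["death_date"].to_numpy().astype("datetime64[D]")
    death = np.where(np.isnat(death_d), np.inf, death_d.astype("int64").astype(float))
    first = grouped["min"].to_numpy()
    horizon = np.minimum(
        np.minimum(grouped["max"].to_numpy() + DUE_INTERVAL_DAYS, end_ord),
        death[pos],
    )
    n_windows = (np.floor((horizon - first) / DUE_INTERVAL_DAYS) + 1).astype(int)
    n_windows = np.maximum(n_windows, 0)

    total = int(n_windows.sum())
    row = np.repeat(np.arange(len(grouped)), n_windows)
    k = np.arange(total) - np.repeat(np.cumsum(n_windows) - n_windows, n_windows)
    due_ord = first[row] + DUE_INTERVAL_DAYS * k

    logits = (
        config.baseline_miss_logit + offsets[pos[row]] + _shock_logits(due_ord, config)
    )
    attended = rng.random(total) >= expit(logits)

    blood_pid = np.repeat(grouped["patient_id"].to_numpy()[row[attended]], len(BLOOD_TESTS))
    blood_ord = np.repeat(due_ord[attended], len(BLOOD_TESTS))
    blood_type = np.tile(np.asarray(BLOOD_TESTS), int(attended.sum()))

    lef = grouped["drug"].to_numpy()[row] == "leflunomide"
    bp_logits = logits[lef] + config.bp_extra_miss_logit
    bp_attended = rng.random(int(lef.sum())) >= expit(bp_logits)
    bp_pid = grouped["patient_id"].to_numpy()[row[lef]][bp_attended]
    bp_ord = due_ord[lef][bp_attended]

    frame = pd.DataFrame(
        {
            "patient_id": np.concatenate([blood_pid, bp_pid]),
            "test_type": np.concatenate(
                [blood_type, np.full(len(bp_pid), "BP")]
            ),
            "date": pd.to_datetime(
                np.concatenate([blood_ord, bp_ord]).astype("datetime64[D]")
            ),
        }
    )
    frame = frame.sort_values(TEST_COLUMNS, kind="mergesort")
    return frame.reset_index(drop=True)[TEST_COLUMNS]


# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> MonitoringData:
    """Run all three stages with independent sub-streams of ``config.seed``."""
    patients = generate_population(config)
    prescriptions = generate_prescribing(patients, config)
    tests = generate_tests(patients, prescriptions, config)
    return MonitoringData(patients=patients, prescriptions=prescriptions, tests=tests)
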