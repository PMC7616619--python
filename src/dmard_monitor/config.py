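"""Simulation configuration for the synthetic primary-care EHR generator.

The defaults describe a prevalent cohort of patients on long-term
immunosuppressant (DMARD) repeat prescribing, monitored on a nominal
3-monthly cycle, with a transient service disruption beginning late March
2020 that raises the per-window probability of missed monitoring and then
decays back to baseline.  Demographic marginals default to the composition
of a national English primary-care DMARD cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from datetime import date

import yaml

from .errors import ConfigurationError

DRUGS = ("azathioprine", "leflunomide", "methotrexate")

AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

REGIONS = (
    "East",
    "East Midlands",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire and The Humber",
)

#: Subgroup columns of the patient table, in reporting order.
SUBGROUP_COLUMNS = (
    "age_band",
    "sex",
    "ethnicity",
    "region",
    "imd_quintile",
    "rural_urban",
    "care_home",
    "dementia",
    "housebound",
    "learning_disability",
    "serious_mental_illness",
)


def _norm(weights: dict) -> dict:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


def _default_demographics() -> dict:
    # Category weights follow the composition of a national English
    # primary-care DMARD cohort (counts rounded to the nearest 5).
    return {
        "age_band": _norm(
            {
                "18-29": 3465,
                "30-39": 5905,
                "40-49": 9555,
                "50-59": 18050,
                "60-69": 22410,
                "70-79": 23490,
                "80+": 11730,
            }
        ),
        "sex": _norm({"female": 57620, "male": 36990}),
        "ethnicity": _norm(
            {
                "Black": 1050,
                "Mixed": 625,
                "Other": 750,
                "South Asian": 5180,
                "White": 86215,
                "missing": 790,
            }
        ),
        "region": _norm(
            {
                "East": 23105,
                "East Midlands": 16365,
                "London": 3040,
                "North East": 5040,
                "North West": 7860,
                "South East": 6605,
                "South West": 15260,
                "West Midlands": 2925,
                "Yorkshire and The Humber": 14140,
                "missing": 270,
            }
        ),
        "imd_quintile": _norm({1: 15160, 2: 17555, 3: 21210, 4: 21075, 5: 19610}),
        "rural_urban": _norm(
            {1: 14435, 2: 6155, 3: 49290, 4: 235, 5: 13180, 6: 630, 7: 9855, 8: 835}
        ),
        "care_home": _norm({True: 575, False: 94035}),
        "dementia": _norm({True: 1370, False: 93245}),
        "housebound": _norm({True: 3380, False: 91235}),
        "learning_disability": _norm({True: 375, False: 94235}),
        "serious_mental_illness": _norm({True: 940, False: 93670}),
    }


def _default_subgroup_effects() -> dict:
    # Logit offsets on the per-window miss probability.  Signs follow the
    # qualitative pattern of missed monitoring in English primary care:
    # younger patients, more deprived/urban areas and patients with a
    # serious mental illness or learning disability miss more often;
    # care-home/dementia/housebound status makes little difference.
    return {
        ("age_band", "18-29"): 0.50,
        ("age_band", "30-39"): 0.35,
        ("age_band", "40-49"): 0.20,
        ("age_band", "50-59"): 0.10,
        ("age_band", "60-69"): 0.0,
        ("age_band", "70-79"): -0.05,
        ("age_band", "80+"): 0.0,
        ("region", "London"): 0.20,
        ("region", "North West"): 0.15,
        ("region", "West Midlands"): 0.10,
        ("region", "South East"): -0.05,
        ("region", "South West"): -0.10,
        ("region", "North East"): -0.10,
        ("ethnicity", "Black"): 0.25,
        ("ethnicity", "Mixed"): 0.20,
        ("ethnicity", "South Asian"): 0.20,
        ("ethnicity", "Other"): 0.15,
        ("imd_quintile", 1): 0.20,
        ("imd_quintile", 2): 0.10,
        ("imd_quintile", 4): -0.05,
        ("imd_quintile", 5): -0.10,
        ("serious_mental_illness", True): 0.30,
        ("learning_disability", True): 0.30,
    }


def logit(p: float) -> float:
    """Log-odds of a probability in (0, 1)."""
    return math.log(p / (1.0 - p))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic EHR generator.

    Probabilities act on the per-due-window miss mechanism through a
    logistic model: ``pi = expit(baseline_miss_logit + practice effect +
    subgroup offsets + patient frailty + shock(t))``.
    """

    n_patients: int = 5000
    n_practices: int = 100
    study_start: date = date(2019, 9, 1)
    study_end: date = date(2022, 7, 31)
    #: Marginal probability of being on each drug as the primary therapy.
    drug_prevalence: dict = field(
        default_factory=lambda: {
            "methotrexate": 0.63,
            "azathioprine": 0.25,
            "leflunomide": 0.06,
        }
    )
    #: Probability that an on-drug patient also receives a second DMARD.
    combination_therapy_rate: float = 0.02
    prescription_interval_days: int = 84
    prescription_interval_sd: float = 7.0
    #: Probability of stopping the drug at each repeat-prescribing interval.
    discontinuation_hazard: float = 0.01
    baseline_miss_logit: float = logit(0.28)
    #: Extra miss propensity of the blood-pressure check (leflunomide only).
    bp_extra_miss_logit: float = 0.8
    lockdown_shock_logit: float = logit(0.41) - logit(0.28)
    shock_start: date = date(2020, 3, 23)
    shock_end: date = date(2020, 6, 30)
    recovery_end: date = date(2020, 9, 30)
    practice_effect_sd: float = 0.8
    #: Optional patient-level frailty (SD of a normal logit offset).
    patient_frailty_sd: float = 0.0
    subgroup_effects: dict = field(default_factory=_default_subgroup_effects)
    demographic_distributions: dict = field(default_factory=_default_demographics)
    #: Fraction of patients with an injected missing core field
    #: (age/sex/IMD/rurality) to exercise the exclusion rule.
    missing_core_fraction: float = 0.0
    annual_death_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be a positive integer")
        if self.n_practices <= 0:
            raise ConfigurationError("n_practices must be a positive integer")
        if not self.study_start < self.shock_start:
            raise ConfigurationError("study_start must precede shock_start")
        if not self.shock_start < self.shock_end:
            raise ConfigurationError("shock_start must precede shock_end")
        if not self.shock_end <= self.recovery_end:
            raise ConfigurationError("shock_end must not exceed recovery_end")
        if not self.recovery_end <= self.study_end:
            raise ConfigurationError("recovery_end must not exceed study_end")
        for name in (
            "combination_therapy_rate",
            "discontinuation_hazard",
            "missing_core_fraction",
            "annual_death_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.prescription_interval_days <= 0:
            raise ConfigurationError("prescription_interval_days must be positive")
        if self.prescription_interval_sd < 0:
            raise ConfigurationError("prescription_interval_sd must be non-negative")
        if self.practice_effect_sd < 0:
            raise ConfigurationError("practice_effect_sd must be non-negative")
        if self.patient_frailty_sd < 0:
            raise ConfigurationError("patient_frailty_sd must be non-negative")
        total_prev = 0.0
        for drug, p in self.drug_prevalence.items():
            if drug not in DRUGS:
                raise ConfigurationError(f"drug_prevalence: unknown drug {drug!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"drug_prevalence[{drug!r}] must lie in [0, 1], got {p!r}"
                )
            total_prev += p
        if total_prev > 1.0 + 1e-9:
            raise ConfigurationError(
                "drug_prevalence probabilities must sum to at most 1"
            )
        missing_groups = set(SUBGROUP_COLUMNS) - set(self.demographic_distributions)
        if missing_groups:
            raise ConfigurationError(
                f"demographic_distributions is missing groups {sorted(missing_groups)}"
            )
        for (group, _cat) in self.subgroup_effects:
            if group not in SUBGROUP_COLUMNS:
                raise ConfigurationError(
                    f"subgroup_effects: unknown group {group!r}"
                )
        for group, dist in self.demographic_distributions.items():
            s = 0.0
            for cat, p in dist.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"demographic_distributions[{group!r}][{cat!r}] "
                        f"must lie in [0, 1], got {p!r}"
                    )
                s += p
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"demographic_distributions[{group!r}] probabilities "
                    f"sum to {s!r}, not 1"
                )

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        """JSON/YAML-safe snapshot of the configuration."""
        out: dict = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, date):
                v = v.isoformat()
            elif f.name == "subgroup_effects":
                nested: dict = {}
                for (group, cat), off in v.items():
                    nested.setdefault(group, {})[str(cat)] = off
                v = nested
            elif f.name == "demographic_distributions":
                v = {g: {str(c): p for c, p in d.items()} for g, d in v.items()}
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for key, value in raw.items():
            if key not in known:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            if key in ("study_start", "study_end", "shock_start", "shock_end",
                       "recovery_end") and isinstance(value, str):
                value = date.fromisoformat(value)
            if key == "subgroup_effects" and isinstance(value, dict):
                flat = {}
                for group, cats in value.items():
                    if not isinstance(cats, dict):
                        raise ConfigurationError(
                            "subgroup_effects must map group -> category -> offset"
                        )
                    for cat, off in cats.items():
                        flat[(group, _coerce_category(group, cat))] = float(off)
                value = flat
            if key == "demographic_distributions" and isinstance(value, dict):
                value = {
                    g: {_coerce_category(g, c): float(p) for c, p in d.items()}
                    for g, d in value.items()
                }
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)


def _coerce_category(group: str, cat):
    """Normalise category keys read from YAML/JSON to their native types."""
    if isinstance(cat, str):
        if group in ("imd_quintile", "rural_urban"):
            try:
                return int(cat)
            except ValueError:
                return cat
        if cat in ("True", "true"):
            return True
        if cat in ("False", "false"):
            return False
    return cat
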