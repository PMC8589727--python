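"""Seeded generator of linked EHR tables with the statistical structure the
analysis assumes.

The generator emulates a primary-care cohort in which a configurable
fraction of patients carries prevalent chronic liver disease (six subtypes),
cardiovascular indications arrive as incident events *after* the first liver
diagnosis, and prescribing of the indicated antithrombotic class follows
liver-status-specific probabilities. Refill streams follow one of four
adherence archetypes:

* ``primary_nonadherent`` — exactly one prescription, never refilled
* ``steady_refiller``     — refills at ~Normal(mean, sd) intervals, truncated ≥1 day
* ``irregular_refiller``  — a mixture of short and long (> supply) intervals
* ``early_discontinuer``  — a Geometric number of refills, then stops

Warfarin users receive an AR(1) INR series sampled every 14–42 days; labs
sufficient for Child-Pugh and FIB-4 are emitted around the indication date;
stroke and bleeding outcomes are drawn from exponential hazards multiplied
by the configured uncovered-time-category and per-10%-PDC effects. A fixed
seed reproduces byte-identical tables.

The generator keeps an internal bookkeeping ("truth") table of everything it
drew — liver status, indication, archetype, planted prior exposure, switch —
so downstream modules can be checked against the generating process exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ehr_core import (
    ANTICOAGULANTS,
    ANTIPLATELETS,
    Condition,
    DrugClass,
    INDICATIONS,
    StudyConfig,
)
from .risk_models import UNCOVERED_CATEGORIES

REGIONS = (
    "North East", "North West", "Yorkshire and the Humber", "East Midlands",
    "West Midlands", "East of England", "London", "South East", "South West",
)

ARCHETYPES = ("primary_nonadherent", "steady_refiller", "irregular_refiller", "early_discontinuer")

LIVER_SUBTYPE_ORDER = ("ALD", "autoimmune_liver_disease", "cirrhosis", "HBV", "HCV", "NAFLD")

_ANTICOAG_WEIGHTS = {
    "warfarin": 0.60, "rivaroxaban": 0.16, "apixaban": 0.14, "dabigatran": 0.06, "edoxaban": 0.04,
}
_ANTIPLAT_WEIGHTS = {
    "aspirin": 0.70, "clopidogrel": 0.22, "dipyridamole": 0.05, "prasugrel": 0.015, "ticagrelor": 0.015,
}


class GeneratorConfig(BaseModel):
    """Tunable structure of the synthetic cohort.

    Prescribing probabilities default to the liver / non-liver prescribing
    prevalences the analysis is designed around (≈0.21 vs 0.34 for
    anticoagulants, ≈0.56 vs 0.71 for antiplatelets); liver subtype weights
    default to the relative sizes of the six subtype cohorts; the stroke
    category multipliers and the bleeding per-10%-PDC multiplier default to
    the effect structure the stroke/bleeding models are meant to recover.
    """

    n_patients: int = Field(2000, gt=0)
    liver_prevalence: float = Field(0.30, ge=0, le=1)
    liver_subtype_weights: tuple[float, float, float, float, float, float] = (
        0.29, 0.06, 0.32, 0.03, 0.04, 0.26
    )
    indication_rate: float = Field(0.10, gt=0)  # per-year hazard of incident CVD
    p_prescribed: Mapping[str, Mapping[str, float]] = {
        "anticoagulant": {"with_liver_disease": 0.206, "without_liver_disease": 0.335},
        "antiplatelet": {"with_liver_disease": 0.562, "without_liver_disease": 0.711},
    }
    p_prior_exposure: float = Field(0.0, ge=0, le=1)  # planted pre-indication prescriptions
    archetype_weights: tuple[float, float, float, float] = (0.06, 0.40, 0.30, 0.24)
    refill_mean_days: Mapping[str, float] = {
        "steady_refiller": 30.0, "irregular_refiller": 26.0, "early_discontinuer": 30.0,
    }
    refill_sd_days: Mapping[str, float] = {
        "steady_refiller": 4.0, "irregular_refiller": 8.0, "early_discontinuer": 5.0,
    }
    irregular_long_mean_days: float = 80.0
    irregular_long_sd_days: float = 25.0
    irregular_p_long: float = Field(0.35, ge=0, le=1)
    early_mean_refills: float = Field(3.0, gt=0)
    switch_probability: float = Field(0.10, ge=0, le=1)
    inr_mean: float = Field(2.5, gt=0)
    inr_sd: float = Field(0.5, gt=0)
    inr_ar1: float = Field(0.7, ge=0, lt=1)
    stroke_base_hazard: float = Field(0.02, gt=0)  # per-year
    stroke_hr_by_uncovered_category: tuple[float, float, float, float, float] = (
        1.0, 1.0, 1.05, 1.22, 1.20
    )
    bleed_base_hazard: float = Field(0.03, gt=0)  # per-year
    bleed_hr_per_10pct_pdc: float = Field(1.18, gt=0)
    death_rate: float = Field(0.03, gt=0)  # per-year
    censor_rate: float = Field(0.03, gt=0)  # per-year deregistration hazard
    seed: int = 0

    @model_validator(mode="after")
    def _check_weights(self) -> "GeneratorConfig":
        for name, w in (("liver_subtype_weights", self.liver_subtype_weights),
                        ("archetype_weights", self.archetype_weights)):
            if any(x < 0 for x in w):
                raise ValueError(f"{name} must be non-negative")
            if sum(w) <= 0:
                raise ValueError(f"{name} must have a positive sum")
        for cls, by_status in self.p_prescribed.items():
            DrugClass(cls)
            for p in by_status.values():
                if not 0 <= p <= 1:
                    raise ValueError("p_prescribed entries must be probabilities")
        return self


@dataclass
class SyntheticCohort:
    """The four generated tables plus the generator's bookkeeping."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _refill_intervals(rng: np.random.Generator, archetype: str, cfg: GeneratorConfig, horizon_days: int) -> list[int]:
    """Inter-issue intervals (days) for one patient; total span ≤ horizon."""
    if archetype == "primary_nonadherent":
        return []
    mean = cfg.refill_mean_days[archetype]
    sd = cfg.refill_sd_days[archetype]
    intervals: list[int] = []
    if archetype == "early_discontinuer":
        n_refills = int(rng.geometric(1.0 / cfg.early_mean_refills))
        total = 0
        for _ in range(n_refills):
            step = max(1, int(round(rng.normal(mean, sd)))) if sd > 0 else max(1, int(round(mean)))
            if total + step >= horizon_days:
                break
            intervals.append(step)
            total += step
        return intervals
    total = 0
    while True:
        if archetype == "irregular_refiller" and rng.random() < cfg.irregular_p_long:
            step = rng.normal(cfg.irregular_long_mean_days, cfg.irregular_long_sd_days)
        else:
            step = rng.normal(mean, sd) if sd > 0 else mean
        step = max(1, int(round(step)))
        if total + step >= horizon_days:
            return intervals
        intervals.append(step)
        total += step


def _lab_value(rng: np.random.Generator, analyte: str, liver: bool) -> float:
    if analyte == "bilirubin_total":
        v = rng.lognormal(np.log(1.4), 0.6) if liver else rng.lognormal(np.log(0.7), 0.3)
        return float(max(0.05, v))
    if analyte == "albumin":
        v = rng.normal(3.3, 0.6) if liver else rng.normal(4.1, 0.35)
        return float(min(6.0, max(1.2, v)))
    if analyte == "AST":
        v = rng.lognormal(np.log(55), 0.5) if liver else rng.lognormal(np.log(26), 0.35)
        return float(max(5.0, v))
    if analyte == "ALT":
        v = rng.lognormal(np.log(45), 0.5) if liver else rng.lognormal(np.log(24), 0.35)
        return float(max(5.0, v))
    if analyte == "platelets":
        v = rng.normal(170, 70) if liver else rng.normal(255, 55)
        return float(max(20.0, v))
    raise ValueError(analyte)


_COMORBIDITY_P = {
    "hypertension": 0.45,
    "diabetes": 0.22,
    "heart_failure": 0.12,
    "chronic_kidney_disease": 0.12,
    "proton_pump_inhibitor_use": 0.30,
    "vascular_disease": 0.15,
}
_LIVER_COMPLICATION_P = {"ascites": 0.12, "hepatic_encephalopathy": 0.06, "varices": 0.10}


def generate_cohort(config: GeneratorConfig, study: Optional[StudyConfig] = None) -> SyntheticCohort:
    """Generate the four linked tables for ``config.n_patients`` people.

    Structural guarantees: every liver patient's earliest liver diagnosis
    precedes any generated CVD indication; no same-class prescription before
    the indication except explicitly planted prior exposure
    (``p_prior_exposure``); refill streams follow the drawn archetype;
    identical seeds give identical tables.
    """
    study = study or StudyConfig()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(study.study_start)
    admin = pd.Timestamp(study.admin_censor_date)

    sub_w = np.asarray(config.liver_subtype_weights, dtype=float)
    sub_w = sub_w / sub_w.sum()
    arch_w = np.asarray(config.archetype_weights, dtype=float)
    arch_w = arch_w / arch_w.sum()

    patients, prescriptions, diagnoses, labs, truth = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "female" if rng.random() < 0.5 else "male"
        region = REGIONS[int(rng.integers(len(REGIONS)))]
        reg_start = start + pd.Timedelta(days=int(rng.integers(0, 3650)))
        age_at_reg = int(rng.integers(30, 81))
        birth_year = reg_start.year - age_at_reg

        death_wait = min(rng.exponential(365.25 / config.death_rate), 40000.0)
        death = reg_start + pd.Timedelta(days=int(death_wait) + 1)
        death_date = death if death <= admin + pd.Timedelta(days=365) else None
        dereg_wait = min(rng.exponential(365.25 / config.censor_rate), 40000.0)
        dereg = reg_start + pd.Timedelta(days=int(dereg_wait) + 1)
        dereg_date = dereg if dereg < admin else None
        fu_candidates = [admin] + [d for d in (death_date, dereg_date) if d is not None]
        raw_fu_end = min(fu_candidates)

        liver = rng.random() < config.liver_prevalence
        liver_first = None
        subtypes: list[str] = []
        if liver:
            n_sub = 2 if rng.random() < 0.15 else 1
            idx = rng.choice(len(LIVER_SUBTYPE_ORDER), size=n_sub, replace=False, p=sub_w)
            subtypes = [LIVER_SUBTYPE_ORDER[int(j)] for j in idx]
            liver_first = reg_start + pd.Timedelta(days=int(rng.integers(90, 1500)))
            diagnoses.append((pid, liver_first, subtypes[0], "primary_care"))
            for s in subtypes[1:]:
                diagnoses.append((pid, liver_first + pd.Timedelta(days=int(rng.integers(1, 900))), s, "primary_care"))

        drug_class = "anticoagulant" if rng.random() < 0.5 else "antiplatelet"
        anchor = liver_first if liver else reg_start + pd.Timedelta(days=int(rng.integers(0, 1000)))
        wait_days = min(rng.exponential(365.25 / config.indication_rate), 40000.0)
        indication_date = anchor + pd.Timedelta(days=int(wait_days) + 1)
        has_indication = indication_date < raw_fu_end - pd.Timedelta(days=1)

        indication_condition = None
        if has_indication:
            if drug_class == "anticoagulant":
                indication_condition = Condition.atrial_fibrillation.value
            else:
                opts = sorted(c.value for c in INDICATIONS[DrugClass.antiplatelet])
                indication_condition = opts[int(rng.integers(len(opts)))]
            diagnoses.append((pid, indication_date, indication_condition, "secondary_care"))

            # comorbidities before the indication
            for cond, p in _COMORBIDITY_P.items():
                if rng.random() < p:
                    span = max(2, int((indication_date - reg_start).days))
                    diagnoses.append((pid, reg_start + pd.Timedelta(days=int(rng.integers(1, span))), cond, "primary_care"))
            if liver:
                for cond, p in _LIVER_COMPLICATION_P.items():
                    if rng.random() < p:
                        span = max(2, int((indication_date - liver_first).days))
                        diagnoses.append((pid, liver_first + pd.Timedelta(days=int(rng.integers(0, span))), cond, "primary_care"))

            # labs around the indication (Child-Pugh / FIB-4 inputs)
            for analyte in ("bilirubin_total", "albumin", "AST", "ALT", "platelets"):
                lab_date = indication_date + pd.Timedelta(days=int(rng.integers(-90, 31)))
                labs.append((pid, max(lab_date, reg_start), analyte, round(_lab_value(rng, analyte, liver), 2)))
            base_inr = float(np.clip(rng.normal(1.2, 0.25), 0.8, 2.2))
            labs.append((pid, indication_date - pd.Timedelta(days=int(rng.integers(0, 90))), "INR", round(base_inr, 2)))

        drug_weights = _ANTICOAG_WEIGHTS if drug_class == "anticoagulant" else _ANTIPLAT_WEIGHTS
        drug_names = list(drug_weights)
        drug_p = np.asarray(list(drug_weights.values()))
        drug_p = drug_p / drug_p.sum()

        prior_exposure = False
        if has_indication and rng.random() < config.p_prior_exposure:
            prior_exposure = True
            offset = int(rng.integers(100, 800))
            prior_date = indication_date - pd.Timedelta(days=offset)
            if prior_date <= reg_start:
                prior_date = reg_start + pd.Timedelta(days=1)
            prior_drug = drug_names[int(rng.choice(len(drug_names), p=drug_p))]
            prescriptions.append((pid, prior_date, prior_drug))

        prescribed = bool(
            has_indication
            and rng.random()
            < config.p_prescribed[drug_class][
                "with_liver_disease" if liver else "without_liver_disease"
            ]
        )
        archetype = None
        index_date = index_drug = switch_date = switch_drug = None
        n_issues = 0
        if prescribed:
            index_date = indication_date + pd.Timedelta(days=int(rng.integers(0, 31)))
            if index_date >= raw_fu_end:
                index_date = raw_fu_end - pd.Timedelta(days=1)
            index_drug = drug_names[int(rng.choice(len(drug_names), p=drug_p))]
            archetype = ARCHETYPES[int(rng.choice(len(ARCHETYPES), p=arch_w))]
            horizon = int((raw_fu_end - index_date).days)
            intervals = _refill_intervals(rng, archetype, config, horizon)
            issue_days = np.concatenate([[0], np.cumsum(intervals)]).astype(int) if intervals else np.array([0])
            n_issues = len(issue_days)
            drugs_seq = [index_drug] * n_issues
            if n_issues >= 2 and rng.random() < config.switch_probability:
                j = int(rng.integers(1, n_issues))
                others = [d for d in drug_names if d != index_drug]
                switch_drug = others[int(rng.integers(len(others)))]
                for k in range(j, n_issues):
                    drugs_seq[k] = switch_drug
                switch_date = index_date + pd.Timedelta(days=int(issue_days[j]))
            for d, drg in zip(issue_days, drugs_seq):
                prescriptions.append((pid, index_date + pd.Timedelta(days=int(d)), drg))

            if index_drug == "warfarin":
                day = int(rng.integers(14, 43))
                horizon_inr = min(horizon, 730)
                x = config.inr_mean + rng.normal(0, config.inr_sd)
                innov_sd = config.inr_sd * np.sqrt(1 - config.inr_ar1**2)
                while day < horizon_inr:
                    x = config.inr_mean + config.inr_ar1 * (x - config.inr_mean) + rng.normal(0, innov_sd)
                    labs.append((pid, index_date + pd.Timedelta(days=day), "INR", round(float(np.clip(x, 0.6, 19.5)), 2)))
                    day += int(rng.integers(14, 43))

        patients.append(
            (
                pid, sex, birth_year, region, reg_start,
                dereg_date, death_date, None,
            )
        )
        truth.append(
            {
                "patient_id": pid,
                "liver": liver,
                "liver_subtypes": ";".join(sorted(subtypes)),
                "liver_first_date": liver_first,
                "drug_class": drug_class,
                "has_indication": has_indication,
                "indication_condition": indication_condition,
                "indication_date": indication_date if has_indication else None,
                "prior_exposure": prior_exposure,
                "prescribed": prescribed,
                "index_date": index_date,
                "index_drug": index_drug,
                "archetype": archetype,
                "n_issues": n_issues,
                "switch_date": switch_date,
                "switch_drug": switch_drug,
                "raw_followup_end": raw_fu_end,
            }
        )

    patients_df = pd.DataFrame(
        patients,
        columns=[
            "patient_id", "sex", "birth_year", "region", "registration_start",
            "registration_end", "death_date", "practice_last_collection",
        ],
    )
    for c in ("registration_start", "registration_end", "death_date", "practice_last_collection"):
        patients_df[c] = pd.to_datetime(patients_df[c])
    rx_df = pd.DataFrame(prescriptions, columns=["patient_id", "issue_date", "drug"])
    rx_df = rx_df.sort_values(["patient_id", "issue_date", "drug"], kind="stable").reset_index(drop=True)
    dx_df = pd.DataFrame(diagnoses, columns=["patient_id", "event_date", "condition", "source"])
    dx_df = dx_df.sort_values(["patient_id", "event_date", "condition"], kind="stable").reset_index(drop=True)
    labs_df = pd.DataFrame(labs, columns=["patient_id", "date", "analyte", "value"])
    labs_df = labs_df.sort_values(["patient_id", "date", "analyte"], kind="stable").reset_index(drop=True)
    truth_df = pd.DataFrame(truth)
    return SyntheticCohort(patients_df, rx_df, dx_df, labs_df, truth_df, config)


# --- outcome simulation ---------------------------------------------------

_DAYS_PER_YEAR = 365.25


def simulate_summaries(
    n: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    category_probs: Optional[np.ndarray] = None,
    followup_range_days: tuple[int, int] = (365, 1826),
) -> pd.DataFrame:
    """Draw per-patient exposure summaries (uncovered category, PDC, follow-up)
    for outcome simulation and parameter-recovery studies."""
    if category_probs is None:
        category_probs = np.full(len(UNCOVERED_CATEGORIES), 1 / len(UNCOVERED_CATEGORIES))
    cats = rng.choice(len(UNCOVERED_CATEGORIES), size=n, p=category_probs)
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:06d}" for i in range(n)],
            "uncovered_category": [UNCOVERED_CATEGORIES[c] for c in cats],
            "pdc": rng.uniform(0.0, 1.0, size=n),
            "followup_days": rng.integers(followup_range_days[0], followup_range_days[1], size=n),
        }
    )


def generate_outcomes(
    summaries: pd.DataFrame,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate stroke and bleeding outcomes for exposure summaries.

    Stroke: exponential with hazard = ``stroke_base_hazard`` × the category
    multiplier of the patient's uncovered-time category. Bleeding:
    exponential with hazard = ``bleed_base_hazard`` ×
    ``bleed_hr_per_10pct_pdc``^(PDC × 10). Both censored at follow-up end.

    Returns the summaries with ``stroke_time_days``/``stroke_event`` and
    ``bleed_time_days``/``bleed_event`` columns appended.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    mult = dict(zip(UNCOVERED_CATEGORIES, config.stroke_hr_by_uncovered_category))
    out = summaries.copy()
    fu = out["followup_days"].to_numpy(dtype=float)

    stroke_rate = config.stroke_base_hazard / _DAYS_PER_YEAR * out["uncovered_category"].map(mult).to_numpy(dtype=float)
    t_stroke = rng.exponential(1.0 / stroke_rate)
    out["stroke_event"] = t_stroke < fu
    out["stroke_time_days"] = np.minimum(t_stroke, fu)

    bleed_rate = (
        config.bleed_base_hazard / _DAYS_PER_YEAR
        * config.bleed_hr_per_10pct_pdc ** (out["pdc"].to_numpy(dtype=float) * 10.0)
    )
    t_bleed = rng.exponential(1.0 / bleed_rate)
    out["bleed_event"] = t_bleed < fu
    out["bleed_time_days"] = np.minimum(t_bleed, fu)
    return out


def outcomes_to_diagnoses(outcomes: pd.DataFrame, index_dates: pd.Series) -> pd.DataFrame:
    """Convert simulated outcome times to diagnosis events (secondary care)."""
    rows = []
    for _, r in outcomes.iterrows():
        idx = index_dates.get(r["patient_id"])
        if idx is None or pd.isna(idx):
            continue
        if r["stroke_event"]:
            rows.append((r["patient_id"], idx + pd.Timedelta(days=int(r["stroke_time_days"])), "stroke_ischaemic", "secondary_care"))
        if r["bleed_event"]:
            rows.append((r["patient_id"], idx + pd.Timedelta(days=int(r["bleed_time_days"])), "bleeding_nonfatal", "secondary_care"))
    return pd.DataFrame(rows, columns=["patient_id", "event_date", "condition", "source"])
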