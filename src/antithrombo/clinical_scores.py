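"""Severity and risk scores at the index date: Child-Pugh, FIB-4, CHA₂DS₂-VASc.

Child-Pugh grades liver decompensation from five components (total
bilirubin, serum albumin, INR, ascites, hepatic encephalopathy), each scored
1–3; the sum (5–15) maps to class A (5–6), B (7–9) or C (10–15). FIB-4 is
the non-invasive fibrosis index age × AST / (platelets × √ALT) with strata
<1.45, 1.45–3.25 (inclusive) and >3.25. CHA₂DS₂-VASc is the additive stroke
risk score for atrial fibrillation (0–9) with strata 0–1 / 2 / 3–4 / 5–9.

Labs feed the scores through a lookback window around the index date (most
recent qualifying measurement); ascites/encephalopathy presence comes from
the diagnosis stream, scored as 2 points when present unless a severe grade
is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .ehr_core import Analyte, Condition, StudyConfig


class MissingComponentError(ValueError):
    """A score component is unavailable; carries the component names."""

    def __init__(self, components: list[str]):
        super().__init__(f"missing score components: {components}")
        self.components = components


# --- Child-Pugh -----------------------------------------------------------

_CHILD_PUGH_CLASSES = ((5, 6, "A"), (7, 9, "B"), (10, 15, "C"))


def _points_bilirubin(mg_dl: float) -> int:
    return 1 if mg_dl < 2.0 else (2 if mg_dl <= 3.0 else 3)


def _points_albumin(g_dl: float) -> int:
    return 1 if g_dl > 3.5 else (2 if g_dl >= 2.8 else 3)


def _points_inr(inr: float) -> int:
    return 1 if inr < 1.7 else (2 if inr <= 2.3 else 3)


def _points_presence(present: bool, severe: bool) -> int:
    return 1 if not present else (3 if severe else 2)


def child_pugh_class(points: int) -> str:
    for lo, hi, cls in _CHILD_PUGH_CLASSES:
        if lo <= points <= hi:
            return cls
    raise ValueError(f"Child-Pugh points out of range: {points}")


def child_pugh(
    bilirubin_mg_dl: Optional[float],
    albumin_g_dl: Optional[float],
    inr: Optional[float],
    ascites: bool = False,
    encephalopathy: bool = False,
    ascites_severe: bool = False,
    encephalopathy_severe: bool = False,
) -> tuple[int, str]:
    """Child-Pugh points (5–15) and class (A/B/C).

    Component cuts: bilirubin <2 / 2–3 / >3 mg/dL; albumin >3.5 / 2.8–3.5 /
    <2.8 g/dL; INR <1.7 / 1.7–2.3 / >2.3; ascites and encephalopathy 1 when
    absent, 2 when present, 3 when flagged severe. Raises
    :class:`MissingComponentError` naming absent lab components.
    """
    missing = [
        name
        for name, v in (("bilirubin_total", bilirubin_mg_dl), ("albumin", albumin_g_dl), ("INR", inr))
        if v is None or (isinstance(v, float) and math.isnan(v))
    ]
    if missing:
        raise MissingComponentError(missing)
    points = (
        _points_bilirubin(bilirubin_mg_dl)
        + _points_albumin(albumin_g_dl)
        + _points_inr(inr)
        + _points_presence(ascites, ascites_severe)
        + _points_presence(encephalopathy, encephalopathy_severe)
    )
    return points, child_pugh_class(points)


# --- FIB-4 ----------------------------------------------------------------

FIB4_STRATA = ("<1.45", "1.45-3.25", ">3.25")


def fib4_stratum(value: float) -> str:
    if value < 1.45:
        return "<1.45"
    if value <= 3.25:  # middle band closed on both ends
        return "1.45-3.25"
    return ">3.25"


def fib4(age_years: float, ast_u_l: float, platelets_1e9_l: float, alt_u_l: float) -> tuple[float, str]:
    """FIB-4 = age × AST / (platelets × √ALT), with the printed strata."""
    for name, v in (("age", age_years), ("AST", ast_u_l), ("platelets", platelets_1e9_l), ("ALT", alt_u_l)):
        if v is None or not v > 0:
            raise ValueError(f"fib4: nonpositive or missing input '{name}'")
    value = (age_years * ast_u_l) / (platelets_1e9_l * math.sqrt(alt_u_l))
    return value, fib4_stratum(value)


# --- CHA2DS2-VASc ---------------------------------------------------------

CHADSVASC_STRATA = ("0-1", "2", "3-4", "5-9")

#: conditions counting toward the vascular-disease component
_VASCULAR = {
    Condition.vascular_disease.value,
    Condition.myocardial_infarction.value,
    Condition.peripheral_arterial_disease.value,
}
_STROKE_TIA = {
    Condition.stroke_ischaemic.value,
    Condition.transient_ischaemic_attack.value,
}


def chadsvasc_stratum(points: int) -> str:
    if points <= 1:
        return "0-1"
    if points == 2:
        return "2"
    if points <= 4:
        return "3-4"
    return "5-9"


def cha2ds2_vasc(conditions: Iterable[str], sex: str, age_years: float) -> tuple[int, str]:
    """Standard CHA₂DS₂-VASc: CHF 1, hypertension 1, age ≥75 2 (65–74 1),
    diabetes 1, prior stroke/TIA 2, vascular disease 1, female sex 1."""
    conds = set(conditions)
    points = 0
    points += 1 if Condition.heart_failure.value in conds else 0
    points += 1 if Condition.hypertension.value in conds else 0
    points += 1 if Condition.diabetes.value in conds else 0
    points += 2 if conds & _STROKE_TIA else 0
    points += 1 if conds & _VASCULAR else 0
    points += 2 if age_years >= 75 else (1 if age_years >= 65 else 0)
    points += 1 if sex == "female" else 0
    return points, chadsvasc_stratum(points)


# --- per-patient severity profile ----------------------------------------


@dataclass
class SeverityProfile:
    patient_id: str
    child_pugh_points: Optional[int] = None
    child_pugh_class: Optional[str] = None
    fib4_value: Optional[float] = None
    fib4_stratum: Optional[str] = None
    chadsvasc_points: Optional[int] = None
    chadsvasc_stratum: Optional[str] = None
    missing_components: list = field(default_factory=list)


def _latest_lab(labs: pd.DataFrame, analyte: str, index_date, lookback: int, lookahead: int) -> Optional[float]:
    lo = index_date - pd.Timedelta(days=lookback)
    hi = index_date + pd.Timedelta(days=lookahead)
    sub = labs[(labs["analyte"] == analyte) & (labs["date"] >= lo) & (labs["date"] <= hi)]
    if sub.empty:
        return None
    return float(sub.sort_values("date")["value"].iloc[-1])


def score_patient(
    patient_id: str,
    index_date: pd.Timestamp,
    sex: str,
    age_years: float,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> SeverityProfile:
    """All three scores for one patient at the index date.

    Labs: most recent measurement within ``lab_lookback_days`` before (or
    ``lab_lookahead_days`` after) the index. Conditions: any diagnosis on or
    before the index. Scores whose components are missing are left None with
    the components named in ``missing_components``.
    """
    prof = SeverityProfile(patient_id=patient_id)
    conds = set(diagnoses.loc[diagnoses["event_date"] <= index_date, "condition"])

    lb, la = config.lab_lookback_days, config.lab_lookahead_days
    bili = _latest_lab(labs, Analyte.bilirubin_total.value, index_date, lb, la)
    alb = _latest_lab(labs, Analyte.albumin.value, index_date, lb, la)
    inr = _latest_lab(labs, Analyte.INR.value, index_date, lb, la)
    try:
        prof.child_pugh_points, prof.child_pugh_class = child_pugh(
            bili, alb, inr,
            ascites=Condition.ascites.value in conds,
            encephalopathy=Condition.hepatic_encephalopathy.value in conds,
        )
    except MissingComponentError as exc:
        prof.missing_components.extend(exc.components)

    ast = _latest_lab(labs, Analyte.AST.value, index_date, lb, la)
    alt = _latest_lab(labs, Analyte.ALT.value, index_date, lb, la)
    plt = _latest_lab(labs, Analyte.platelets.value, index_date, lb, la)
    if None in (ast, alt, plt):
        prof.missing_components.extend(
            n for n, v in (("AST", ast), ("ALT", alt), ("platelets", plt)) if v is None
        )
    else:
        prof.fib4_value, prof.fib4_stratum = fib4(age_years, ast, plt, alt)

    prof.chadsvasc_points, prof.chadsvasc_stratum = cha2ds2_vasc(conds, sex, age_years)
    return prof


def score_cohort(
    cohort: pd.DataFrame,
    adherence_df: pd.DataFrame,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Severity profiles for every prescribed cohort member, at the index
    (first-prescription) date taken from the adherence table."""
    labs_by = dict(tuple(labs.groupby("patient_id")))
    dx_by = dict(tuple(diagnoses.groupby("patient_id")))
    empty_labs = labs.iloc[0:0]
    empty_dx = diagnoses.iloc[0:0]
    cohort_ix = cohort.set_index("patient_id")
    rows = []
    for _, a in adherence_df.iterrows():
        pid = a["patient_id"]
        m = cohort_ix.loc[pid]
        age = a["index_date"].year - m["birth_year"]
        prof = score_patient(
            pid, a["index_date"], m["sex"], age,
            labs_by.get(pid, empty_labs), dx_by.get(pid, empty_dx), config,
        )
        rows.append(
            {
                "patient_id": pid,
                "age_at_index": age,
                "child_pugh_points": prof.child_pugh_points,
                "child_pugh_class": prof.child_pugh_class,
                "fib4_value": prof.fib4_value,
                "fib4_stratum": prof.fib4_stratum,
                "chadsvasc_points": prof.chadsvasc_points,
                "chadsvasc_stratum": prof.chadsvasc_stratum,
                "missing_components": ";".join(prof.missing_components),
            }
        )
    return pd.DataFrame(rows)
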