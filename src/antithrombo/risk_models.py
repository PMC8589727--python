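"""Risk-model contracts: logistic non-adherence, Cox non-persistence, Cox
stroke risk by uncovered-time category, and Cox bleeding risk per 10% PDC.

Uncovered time — days without medication supply between the index and the
end of follow-up — is a fixed per-patient exposure, categorised as <1 week,
1 week–1 month, 1–3 months, 3–6 months, >6 months (boundary days 7/30/91/183,
left-closed). "<1 week" is the reference category of the stroke models; the
bleeding model reports the hazard ratio per 10-percentage-point increase in
PDC. Logistic fits use statsmodels, Cox fits use lifelines; effects are
exponentiated coefficients with Wald CIs on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from .adherence import SupplyEpisode, covered_days

UNCOVERED_CATEGORIES = (
    "<1 week",
    "1 week to 1 month",
    "1 to 3 months",
    "3 to 6 months",
    ">6 months",
)
_UNCOVERED_BOUNDS = (7, 30, 91, 183)  # left-closed category boundaries, days

AGE_BANDS = ("30-49", "50-59", "60-69", "70-79", "80+")


def age_band(age_years: float) -> str:
    if age_years < 50:
        return "30-49"
    if age_years < 60:
        return "50-59"
    if age_years < 70:
        return "60-69"
    if age_years < 80:
        return "70-79"
    return "80+"


def uncovered_category(uncovered_days: float) -> str:
    """Category of total uncovered time: boundaries <7, [7,30), [30,91), [91,183), ≥183."""
    if uncovered_days < 0:
        raise ValueError("uncovered_days must be non-negative")
    for bound, label in zip(_UNCOVERED_BOUNDS, UNCOVERED_CATEGORIES):
        if uncovered_days < bound:
            return label
    return UNCOVERED_CATEGORIES[-1]


@dataclass(frozen=True)
class UncoveredExposure:
    patient_id: str
    uncovered_days: int
    category: str


def derive_uncovered_exposure(
    episodes: Sequence[SupplyEpisode],
    index_day: int,
    followup_days: int,
    patient_id: str = "",
) -> UncoveredExposure:
    """Days not covered by supply episodes over [index, index + follow-up)."""
    cov = covered_days(episodes, index_day, index_day + followup_days)
    unc = followup_days - cov
    return UncoveredExposure(patient_id, int(unc), uncovered_category(unc))


@dataclass(frozen=True)
class EffectEstimate:
    """One exponentiated model coefficient (OR or HR) with its Wald CI."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


def _drop_degenerate(df: pd.DataFrame, covariates: Sequence[str]) -> list[str]:
    """Remove covariates with a single observed level (separation guard)."""
    kept = []
    for c in covariates:
        if df[c].nunique(dropna=True) > 1:
            kept.append(c)
        else:
            warnings.warn(f"covariate '{c}' has a single level; dropped from the model")
    return kept


def _formula(outcome: str, df: pd.DataFrame, covariates: Sequence[str], references: dict) -> str:
    terms = []
    for c in covariates:
        if c in references:
            terms.append(f"C({c}, Treatment(reference='{references[c]}'))")
        elif df[c].dtype == object or str(df[c].dtype) == "category":
            terms.append(f"C({c})")
        else:
            terms.append(c)
    rhs = " + ".join(terms) if terms else "1"
    return f"{outcome} ~ {rhs}" if outcome else rhs


def _clean_term(term: str) -> str:
    # "C(drug, Treatment(reference='warfarin'))[T.apixaban]" -> "drug[apixaban]"
    if term.startswith("C("):
        inner = term[2:].split(",")[0].split(")")[0]
        level = term.split("[T.")[-1].rstrip("]") if "[T." in term else ""
        return f"{inner}[{level}]" if level else inner
    return term


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    references: Optional[dict] = None,
) -> list[EffectEstimate]:
    """Fully adjusted maximum-likelihood logistic fit; returns ORs with Wald CIs."""
    references = references or {}
    covariates = _drop_degenerate(df, covariates)
    formula = _formula(outcome, df, covariates, references)
    model = smf.logit(formula, data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False)
        except Exception:
            res = model.fit(disp=False, method="bfgs", maxiter=500)
    conf = res.conf_int()
    effects = []
    with np.errstate(over="ignore"):
        for term in res.params.index:
            if term == "Intercept":
                continue
            effects.append(
                EffectEstimate(
                    term=_clean_term(term),
                    estimate=float(np.exp(res.params[term])),
                    ci_low=float(np.exp(conf.loc[term, 0])),
                    ci_high=float(np.exp(conf.loc[term, 1])),
                    p_value=float(res.pvalues[term]),
                )
            )
    return effects


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    references: Optional[dict] = None,
    strata: Optional[str] = None,
) -> tuple[list[EffectEstimate], CoxPHFitter]:
    """Partial-likelihood Cox fit; returns HRs with Wald CIs and the fitter."""
    references = references or {}
    covariates = _drop_degenerate(df, covariates)
    formula = _formula("", df, covariates, references)
    cols = [duration_col, event_col] + list(covariates) + ([strata] if strata else [])
    sub = df[cols].copy()
    # lifelines requires strictly positive durations
    sub = sub[sub[duration_col] > 0]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            sub,
            duration_col=duration_col,
            event_col=event_col,
            formula=formula,
            strata=strata,
        )
    cph._training_frame = sub  # kept for the PH diagnostic
    summ = cph.summary
    effects = [
        EffectEstimate(
            term=_clean_term(str(term)),
            estimate=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
        for term, row in summ.iterrows()
    ]
    return effects, cph


def ph_diagnostic(cph: CoxPHFitter, df_used: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Proportional-hazards diagnostic: scaled Schoenfeld residual correlation
    test against (rank) time, per term."""
    if df_used is None:
        df_used = cph._training_frame
    res = proportional_hazard_test(cph, df_used, time_transform="rank")
    out = res.summary.reset_index()
    out = out.rename(columns={out.columns[0]: "term"})
    return out[["term", "test_statistic", "p"]]


# --- the four model families ---------------------------------------------

NONADHERENCE_REFERENCES = {
    "drug": "warfarin",  # overridden to aspirin for antiplatelet cohorts
    "age_band": "30-49",
    "chadsvasc_stratum": "0-1",
    "child_pugh_class": "A",
    "fib4_stratum": "<1.45",
}

DEFAULT_COVARIATES = (
    "drug",
    "sex",
    "age_band",
    "chronic_kidney_disease",
    "ascites",
    "cirrhosis",
    "hepatic_encephalopathy",
    "varices",
    "proton_pump_inhibitor_use",
    "chadsvasc_stratum",
    "child_pugh_class",
    "fib4_stratum",
)


def _references_for(df: pd.DataFrame, covariates: Sequence[str], drug_reference: str) -> dict:
    refs = dict(NONADHERENCE_REFERENCES)
    refs["drug"] = drug_reference
    return {c: r for c, r in refs.items() if c in covariates and r in set(df.get(c, pd.Series(dtype=object)))}


def fit_nonadherence_model(
    rows: pd.DataFrame,
    outcome: str = "nonadherent",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    drug_reference: str = "warfarin",
) -> list[EffectEstimate]:
    """Multivariable logistic model of non-adherence at a landmark horizon.

    ``rows`` holds one landmark-eligible, non-primary-non-adherent patient
    per row with the boolean outcome and the covariate columns. Reference
    levels: warfarin (or aspirin), age 30–49, CHA₂DS₂-VASc 0–1, Child-Pugh A,
    FIB-4 <1.45.
    """
    rows = rows.copy()
    rows[outcome] = rows[outcome].astype(int)
    covariates = [c for c in covariates if c in rows.columns]
    refs = _references_for(rows, covariates, drug_reference)
    return fit_logistic(rows, outcome, covariates, refs)


def fit_nonpersistence_model(
    rows: pd.DataFrame,
    duration_col: str = "event_time_days",
    event_col: str = "event_flag",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    drug_reference: str = "warfarin",
) -> tuple[list[EffectEstimate], pd.DataFrame]:
    """Cox model of time to discontinuation (switch / follow-up end censored),
    with a proportional-hazards diagnostic per term."""
    rows = rows.copy()
    if rows[event_col].sum() == 0:
        raise ValueError("no discontinuation events; Cox fit undefined")
    covariates = [c for c in covariates if c in rows.columns]
    refs = _references_for(rows, covariates, drug_reference)
    effects, cph = fit_cox(rows, duration_col, event_col, covariates, refs)
    diag = ph_diagnostic(cph)
    return effects, diag


def fit_stroke_model(
    rows: pd.DataFrame,
    duration_col: str = "stroke_time_days",
    event_col: str = "stroke_event",
    strata: Optional[str] = None,
    extra_covariates: Sequence[str] = (),
) -> list[EffectEstimate]:
    """Cox model of ischaemic stroke on uncovered-time category ("<1 week" ref).

    ``strata=chadsvasc_stratum`` reproduces the score-stratified layout; an
    extra ``liver_status`` covariate gives the within-category liver vs
    non-liver contrast.
    """
    covariates = ["uncovered_category"] + [c for c in extra_covariates if c in rows.columns]
    present = set(rows["uncovered_category"])
    missing = [c for c in UNCOVERED_CATEGORIES if c not in present]
    if missing:
        warnings.warn(f"empty uncovered-time categories dropped: {missing}")
    refs = {"uncovered_category": UNCOVERED_CATEGORIES[0]}
    if "liver_status" in covariates:
        refs["liver_status"] = "without_liver_disease"
    effects, _ = fit_cox(rows, duration_col, event_col, covariates, refs, strata=strata)
    return effects


def fit_bleeding_model(
    rows: pd.DataFrame,
    duration_col: str = "bleed_time_days",
    event_col: str = "bleed_event",
    pdc_col: str = "pdc",
    scale: float = 0.10,
) -> EffectEstimate:
    """Cox model of non-fatal bleeding on PDC, reported per 10-percentage-point
    increase (``scale`` = 0.10 of the PDC fraction per unit)."""
    rows = rows.copy()
    rows["pdc_per10"] = rows[pdc_col] / scale
    effects, _ = fit_cox(rows, duration_col, event_col, ["pdc_per10"])
    (eff,) = effects
    return EffectEstimate("pdc_per10", eff.estimate, eff.ci_low, eff.ci_high, eff.p_value)


def effects_frame(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "estimate": e.estimate,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
            }
            for e in effects
        ]
    )
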