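"""End-to-end pipeline: simulate → cohort → prevalence → adherence →
persistence → scores → TTR → risk models, with a reproducibility manifest.

Every stage is a pure function of (inputs, config, seed); ``run_all`` wires
them together, writes CSV result tables and records input/output hashes in a
JSON manifest so that identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import adherence as adh
from . import persistence as per
from .clinical_scores import score_cohort
from .cohort_builder import build_cohort
from .ehr_core import Condition, StudyConfig, write_table
from .inr_ttr import compute_ttr
from .prevalence_stats import prevalence_table
from .risk_models import (
    age_band,
    derive_uncovered_exposure,
    effects_frame,
    fit_bleeding_model,
    fit_nonadherence_model,
    fit_nonpersistence_model,
    fit_stroke_model,
)
from .synthetic_ehr import GeneratorConfig, SyntheticCohort, generate_cohort, generate_outcomes

log = logging.getLogger("antithrombo")

_COMORBIDITY_FLAGS = (
    "chronic_kidney_disease",
    "ascites",
    "cirrhosis",
    "hepatic_encephalopathy",
    "varices",
    "proton_pump_inhibitor_use",
)


def build_covariate_rows(
    cohort: pd.DataFrame,
    adherence_df: pd.DataFrame,
    persistence_df: pd.DataFrame,
    scores_df: pd.DataFrame,
    diagnoses: pd.DataFrame,
    ttr_df: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Merge the derived tables into one model-ready covariate row per patient.

    Covariates follow the model contracts: drug (reference warfarin /
    aspirin), sex, age band, six comorbidity flags at the index date,
    CHA₂DS₂-VASc stratum, Child-Pugh class, FIB-4 stratum, optional
    TTR > 60%; outcomes: the non-adherence flag and the
    discontinuation time/event pair.
    """
    rows = adherence_df.merge(
        persistence_df[
            ["patient_id", "discontinuation_day", "switch_day", "status_6m", "status_12m",
             "event_time_days", "event_flag"]
        ],
        on="patient_id",
        how="left",
    ).merge(scores_df, on="patient_id", how="left")
    cohort_ix = cohort.set_index("patient_id")
    rows["sex"] = rows["patient_id"].map(cohort_ix["sex"])
    rows["age_band"] = rows["age_at_index"].map(age_band)
    dx_by = dict(tuple(diagnoses.groupby("patient_id")))
    for flag in _COMORBIDITY_FLAGS:
        vals = []
        for _, r in rows.iterrows():
            dx = dx_by.get(r["patient_id"])
            present = False
            if dx is not None:
                present = bool(
                    ((dx["condition"] == flag) & (dx["event_date"] <= r["index_date"])).any()
                )
            vals.append(int(present))
        rows[flag] = vals
    if ttr_df is not None and not ttr_df.empty:
        ttr_ix = ttr_df.set_index("patient_id")
        rows["ttr_above_60"] = rows["patient_id"].map(ttr_ix["above_cut"])
    rows["nonadherent"] = (~rows["adherent"].astype(bool)).astype(int)
    rows["child_pugh_class"] = rows["child_pugh_class"].fillna("A")
    rows["fib4_stratum"] = rows["fib4_stratum"].fillna("<1.45")
    return rows


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(
    gen_config: GeneratorConfig,
    study: StudyConfig,
    out_dir: str | Path,
    fit_models: bool = True,
) -> dict:
    """Run the full analysis on a freshly simulated cohort; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": gen_config.seed,
        "generator_config": gen_config.model_dump(mode="json"),
        "study_config": study.model_dump(mode="json"),
        "stages": {},
        "files": {},
    }

    log.info("simulate: n=%d seed=%d", gen_config.n_patients, gen_config.seed)
    syn: SyntheticCohort = generate_cohort(gen_config, study)
    for name, df, kind in (
        ("patients", syn.patients, "patients"),
        ("prescriptions", syn.prescriptions, "prescriptions"),
        ("diagnoses", syn.diagnoses, "diagnoses"),
        ("labs", syn.labs, "labs"),
    ):
        write_table(df, out / f"{name}.csv", kind)
        manifest["stages"][name] = len(df)

    joint_frames = []
    for drug_class, ref_drug in (("anticoagulant", "warfarin"), ("antiplatelet", "aspirin")):
        cohort = build_cohort(
            syn.patients, syn.diagnoses, syn.prescriptions, drug_class, study,
            endpoint_conditions=(Condition.stroke_ischaemic.value,),
        )
        manifest["stages"][f"cohort_{drug_class}"] = len(cohort)
        if cohort.empty:
            continue
        prev = prevalence_table(cohort, syn.prescriptions, z=study.ci_z)
        prev.to_csv(out / f"prevalence_{drug_class}.csv", index=False)

        adh12 = adh.compute_adherence(cohort, syn.prescriptions, study, study.window_12m_days)
        adh6 = adh.compute_adherence(cohort, syn.prescriptions, study, study.window_6m_days)
        adh12.to_csv(out / f"adherence_{drug_class}_12m.csv", index=False)
        adh6.to_csv(out / f"adherence_{drug_class}_6m.csv", index=False)
        pers = per.compute_persistence(cohort, syn.prescriptions, study)
        pers.to_csv(out / f"persistence_{drug_class}.csv", index=False)
        manifest["stages"][f"adherence_{drug_class}"] = len(adh12)
        manifest["stages"][f"persistence_{drug_class}"] = len(pers)

        for landmark, a in (("6m", adh6), ("12m", adh12)):
            jt = per.joint_classification(a, pers, landmark)
            jt.insert(0, "drug_class", drug_class)
            joint_frames.append(jt)

        scores = score_cohort(cohort, adh12, syn.labs, syn.diagnoses, study)
        scores.to_csv(out / f"scores_{drug_class}.csv", index=False)
        ttr_df = None
        if drug_class == "anticoagulant":
            ttr_df = compute_ttr(adh12, syn.labs, study)
            ttr_df.to_csv(out / "ttr.csv", index=False)
            manifest["stages"]["ttr"] = len(ttr_df)

        if fit_models:
            rows = build_covariate_rows(cohort, adh12, pers, scores, syn.diagnoses, ttr_df)
            eligible = rows[rows["eligible"]]
            try:
                effects = fit_nonadherence_model(eligible, drug_reference=ref_drug)
                effects_frame(effects).to_csv(out / f"effects_nonadherence_{drug_class}.csv", index=False)
            except Exception as exc:  # small strata can defeat the fit
                log.warning("non-adherence model (%s) not fitted: %s", drug_class, exc)
            try:
                cox_rows = rows[rows["event_time_days"] > 0]
                effects, diag = fit_nonpersistence_model(cox_rows, drug_reference=ref_drug)
                effects_frame(effects).to_csv(out / f"effects_nonpersistence_{drug_class}.csv", index=False)
                diag.to_csv(out / f"ph_diagnostic_{drug_class}.csv", index=False)
            except Exception as exc:
                log.warning("non-persistence model (%s) not fitted: %s", drug_class, exc)

            # stroke / bleeding: uncovered-time exposure + simulated outcomes
            exp_rows = []
            rx_by = dict(tuple(syn.prescriptions.groupby("patient_id")))
            for _, r in rows.iterrows():
                rx = rx_by.get(r["patient_id"])
                issue_days = sorted(
                    (d - r["index_date"]).days
                    for d in rx["issue_date"]
                    if r["index_date"] <= d
                )
                episodes = adh.build_supply_episodes(issue_days, study.supply_days)
                exp = derive_uncovered_exposure(episodes, 0, max(1, r["followup_days"]), r["patient_id"])
                exp_rows.append(
                    {
                        "patient_id": r["patient_id"],
                        "uncovered_category": exp.category,
                        "pdc": r["pdc"] if np.isfinite(r["pdc"]) else 0.0,
                        "followup_days": max(1, r["followup_days"]),
                    }
                )
            summaries = pd.DataFrame(exp_rows)
            outcomes = generate_outcomes(summaries, gen_config)
            outcomes.to_csv(out / f"outcomes_{drug_class}.csv", index=False)
            try:
                stroke = fit_stroke_model(outcomes)
                effects_frame(stroke).to_csv(out / f"effects_stroke_{drug_class}.csv", index=False)
                bleed = fit_bleeding_model(outcomes)
                effects_frame([bleed]).to_csv(out / f"effects_bleeding_{drug_class}.csv", index=False)
            except Exception as exc:
                log.warning("stroke/bleeding models (%s) not fitted: %s", drug_class, exc)

    if joint_frames:
        pd.concat(joint_frames, ignore_index=True).to_csv(out / "joint_table.csv", index=False)

    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _hash_file(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
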