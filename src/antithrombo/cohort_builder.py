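"""New-user cohort construction: prevalent liver disease, incident CVD
indication, drug-naïve filter and follow-up resolution.

The denominator logic mirrors a new-user, active-comparator design: among
people with prevalent chronic liver disease, only cardiovascular indications
diagnosed strictly *after* the first liver diagnosis qualify (incident with
respect to the liver disease); people with no liver disease contribute their
earliest indication ever. Patients with any same-class prescription before
the indication date are excluded (drug-naïve restriction), and follow-up runs
from the indication to the earliest of endpoint, death, last practice data
collection, deregistration or administrative censoring.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional

import pandas as pd

from .ehr_core import (
    Condition,
    DrugClass,
    INDICATIONS,
    LIVER_CONDITIONS,
    StudyConfig,
    drugs_of_class,
)

LIVER_STATUS = ("with_liver_disease", "without_liver_disease")

#: tie-break priority for follow-up end reasons (highest wins on equal dates)
_REASON_PRIORITY = ["endpoint", "death", "last_collection", "deregistration", "admin_censor"]


def classify_liver_status(diagnoses: pd.DataFrame) -> pd.DataFrame:
    """Per-patient liver status, subtype set and earliest liver diagnosis date.

    A patient is ``with_liver_disease`` iff they have at least one event among
    the six chronic liver conditions; the earliest such event date anchors the
    "prevalent liver disease" clock. Patients may carry several subtypes.

    Returns a DataFrame indexed by ``patient_id`` with columns
    ``liver_status``, ``liver_subtypes`` (sorted ';'-joined string, empty when
    none) and ``liver_first_date`` (NaT when none).
    """
    liver_names = {c.value for c in LIVER_CONDITIONS}
    liver = diagnoses[diagnoses["condition"].isin(liver_names)]
    grouped = liver.groupby("patient_id").agg(
        liver_first_date=("event_date", "min"),
        liver_subtypes=("condition", lambda s: ";".join(sorted(set(s)))),
    )
    grouped["liver_status"] = "with_liver_disease"
    return grouped[["liver_status", "liver_subtypes", "liver_first_date"]]


def find_incident_indication(
    diagnoses: pd.DataFrame,
    liver_first_date: Optional[pd.Timestamp],
    drug_class: DrugClass | str,
) -> Optional[tuple[str, pd.Timestamp]]:
    """Earliest qualifying CVD indication for one patient, or None.

    For anticoagulants the indication is atrial fibrillation; for
    antiplatelets the earliest of MI, PAD, unstable angina or TIA. When the
    patient has prevalent liver disease only events strictly after
    ``liver_first_date`` qualify; a patient whose only qualifying events fall
    on or before the first liver diagnosis has no incident indication in the
    liver cohort.
    """
    wanted = {c.value for c in INDICATIONS[DrugClass(drug_class)]}
    events = diagnoses[diagnoses["condition"].isin(wanted)]
    if liver_first_date is not None and not pd.isna(liver_first_date):
        events = events[events["event_date"] > liver_first_date]
    if events.empty:
        return None
    row = events.sort_values(["event_date", "condition"]).iloc[0]
    return row["condition"], row["event_date"]


def resolve_followup_end(
    patient: Mapping,
    indication_date: pd.Timestamp,
    config: StudyConfig,
    endpoint_date: Optional[pd.Timestamp] = None,
) -> tuple[pd.Timestamp, str]:
    """Earliest of the five censoring anchors, with a fixed reason priority.

    Candidates: primary endpoint, death, last practice data collection,
    deregistration, administrative censoring. Ties on the same date resolve
    by the priority endpoint > death > last_collection > deregistration >
    admin_censor.
    """
    candidates: dict[str, Optional[pd.Timestamp]] = {
        "endpoint": endpoint_date,
        "death": patient.get("death_date"),
        "last_collection": patient.get("practice_last_collection"),
        "deregistration": patient.get("registration_end"),
        "admin_censor": pd.Timestamp(config.admin_censor_date),
    }
    best_date, best_reason = None, None
    for reason in _REASON_PRIORITY:
        date = candidates[reason]
        if date is None or pd.isna(date):
            continue
        if best_date is None or date < best_date:
            best_date, best_reason = date, reason
    assert best_date is not None  # admin censor always present
    return best_date, best_reason


def apply_drug_naive_filter(members: pd.DataFrame, prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Drop members with any same-class prescription strictly before indication.

    The survivors form the prescribing-prevalence denominator. Prescriptions
    of the *other* class do not disqualify (class-specific new-user design).
    """
    if members.empty:
        return members.copy()
    out = []
    rx_by_patient = dict(tuple(prescriptions.groupby("patient_id")))
    for _, m in members.iterrows():
        rx = rx_by_patient.get(m["patient_id"])
        if rx is not None:
            class_drugs = {d.value for d in drugs_of_class(m["indication_class"])}
            prior = rx[rx["drug"].isin(class_drugs) & (rx["issue_date"] < m["indication_date"])]
            if not prior.empty:
                continue
        out.append(m)
    return pd.DataFrame(out, columns=members.columns).reset_index(drop=True)


def build_cohort(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    drug_class: DrugClass | str,
    config: StudyConfig,
    endpoint_conditions: Iterable[str] = (),
    drug_naive: bool = True,
) -> pd.DataFrame:
    """Assemble the per-class cohort table (one row per eligible patient).

    Applies, in order: liver-status classification, incident-indication
    selection (strictly after the first liver diagnosis for liver patients),
    the age ≥ 30 restriction at the indication date, indication within the
    registration window and before follow-up end, and (optionally) the
    drug-naïve filter.

    ``endpoint_conditions`` names diagnosis conditions whose earliest
    occurrence after indication ends follow-up as a primary endpoint.
    """
    drug_class = DrugClass(drug_class)
    liver_info = classify_liver_status(diagnoses)
    dx_by_patient = dict(tuple(diagnoses.groupby("patient_id")))
    endpoint_set = set(endpoint_conditions)

    rows = []
    for _, p in patients.iterrows():
        pid = p["patient_id"]
        dx = dx_by_patient.get(pid)
        if dx is None:
            continue
        if pid in liver_info.index:
            status = "with_liver_disease"
            subtypes = liver_info.at[pid, "liver_subtypes"]
            liver_first = liver_info.at[pid, "liver_first_date"]
        else:
            status, subtypes, liver_first = "without_liver_disease", "", pd.NaT
        found = find_incident_indication(dx, liver_first if status == "with_liver_disease" else None, drug_class)
        if found is None:
            continue
        condition, ind_date = found
        age = ind_date.year - p["birth_year"]
        if age < config.min_age:
            continue
        if ind_date < p["registration_start"]:
            continue
        endpoint_date = None
        if endpoint_set:
            ep = dx[dx["condition"].isin(endpoint_set) & (dx["event_date"] > ind_date)]
            if not ep.empty:
                endpoint_date = ep["event_date"].min()
        fu_end, fu_reason = resolve_followup_end(p, ind_date, config, endpoint_date)
        if ind_date > fu_end:
            continue
        rows.append(
            {
                "patient_id": pid,
                "liver_status": status,
                "liver_subtypes": subtypes,
                "liver_first_date": liver_first,
                "indication_class": drug_class.value,
                "indication_condition": condition,
                "indication_date": ind_date,
                "followup_end": fu_end,
                "followup_end_reason": fu_reason,
                "sex": p["sex"],
                "birth_year": p["birth_year"],
                "region": p["region"],
                "age_at_indication": age,
            }
        )
    members = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "liver_status", "liver_subtypes", "liver_first_date",
            "indication_class", "indication_condition", "indication_date",
            "followup_end", "followup_end_reason", "sex", "birth_year", "region",
            "age_at_indication",
        ],
    )
    if drug_naive:
        members = apply_drug_naive_filter(members, prescriptions)
    return members.reset_index(drop=True)
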