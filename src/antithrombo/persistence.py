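"""Persistence: 90-day-gap discontinuation, in-class switch censoring and
landmark status at 6/12 months, plus the Cox-ready time-to-event table.

A patient is persistent until the interval from the end of an assumed supply
episode to the next issue (or to follow-up end when there is no next issue)
reaches the gap threshold; the discontinuation date is the end of the last
covered episode before the qualifying gap. Switching to a different drug of
the same class censors persistence follow-up rather than counting as
discontinuation; when a switch and a qualifying gap fall on the same day the
switch dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .adherence import SupplyEpisode, build_supply_episodes, classify_primary_nonadherence
from .ehr_core import StudyConfig, drugs_of_class

STATUSES = ("persistent", "non_persistent", "censored_switch", "censored_followup")


def detect_discontinuation(
    episodes: Sequence[SupplyEpisode],
    followup_days: int,
    gap_threshold_days: int = 90,
    gap_from: str = "supply_end",
) -> Optional[int]:
    """Day offset of discontinuation, or None if the patient never discontinues.

    Scans episode ends in order; a gap from an episode end (or the issue date
    when ``gap_from='issue'``) to the next issue, or to follow-up end for the
    last episode, that reaches ``gap_threshold_days`` triggers
    discontinuation at that episode end. The comparison is ``>=`` ("a gap of
    90 days was reached").
    """
    if gap_from not in ("supply_end", "issue"):
        raise ValueError("gap_from must be 'supply_end' or 'issue'")
    for i, ep in enumerate(episodes):
        anchor = ep.end if gap_from == "supply_end" else ep.start
        nxt = episodes[i + 1].start if i + 1 < len(episodes) else followup_days
        if nxt - anchor >= gap_threshold_days:
            return ep.end
    return None


def detect_switch(
    class_rx: pd.DataFrame,
    index_drug: str,
    index_date: pd.Timestamp,
    followup_end: pd.Timestamp,
) -> Optional[pd.Timestamp]:
    """First issue of a same-class drug other than the index drug, within follow-up."""
    other = class_rx[
        (class_rx["drug"] != index_drug)
        & (class_rx["issue_date"] >= index_date)
        & (class_rx["issue_date"] <= followup_end)
    ]
    if other.empty:
        return None
    return other["issue_date"].min()


def landmark_status(
    discontinuation_day: Optional[int],
    switch_day: Optional[int],
    followup_days: int,
    landmark_days: int,
) -> str:
    """Persistence status at a landmark (day offsets from the index date).

    The earliest of {discontinuation, switch, landmark} decides; follow-up
    shorter than the landmark is ``censored_followup`` (the patient is not in
    the landmark denominator). Same-day discontinuation and switch: the
    switch dominates (censoring, not discontinuation).
    """
    if followup_days < landmark_days:
        return "censored_followup"
    d = discontinuation_day if discontinuation_day is not None else landmark_days
    s = switch_day if switch_day is not None else landmark_days
    if s < landmark_days and s <= d:
        return "censored_switch"
    if d < landmark_days:
        return "non_persistent"
    return "persistent"


@dataclass(frozen=True)
class PersistenceResult:
    patient_id: str
    drug: str
    discontinuation_day: Optional[int]
    switch_day: Optional[int]
    status_6m: str
    status_12m: str
    event_time_days: int
    event_flag: bool


def compute_persistence(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-patient persistence table for one cohort (one drug class).

    One row per member with ≥1 class prescription during follow-up:
    discontinuation/switch day offsets from the index (first class
    prescription), landmark statuses at the 6- and 12-month windows, and the
    time-to-discontinuation outcome (``event_time_days``/``event_flag``) with
    switch and follow-up end as censoring.
    """
    rows = []
    rx_by_patient = dict(tuple(prescriptions.groupby("patient_id")))
    for _, m in cohort.iterrows():
        pid = m["patient_id"]
        rx = rx_by_patient.get(pid)
        if rx is None:
            continue
        class_drugs = {d.value for d in drugs_of_class(m["indication_class"])}
        rx = rx[
            rx["drug"].isin(class_drugs)
            & (rx["issue_date"] >= m["indication_date"])
            & (rx["issue_date"] <= m["followup_end"])
        ].sort_values("issue_date")
        if rx.empty:
            continue
        index_date = rx["issue_date"].iloc[0]
        index_drug = rx["drug"].iloc[0]
        primary_na = classify_primary_nonadherence(len(rx))
        followup_days = int((m["followup_end"] - index_date).days)
        switch_date = detect_switch(rx, index_drug, index_date, m["followup_end"])
        switch_day = None if switch_date is None else int((switch_date - index_date).days)
        own = rx[rx["drug"] == index_drug]
        issue_days = [(d - index_date).days for d in own["issue_date"]]
        if switch_day is not None:
            issue_days = [d for d in issue_days if d < switch_day]
        episodes = build_supply_episodes(issue_days, config.supply_days)
        scan_end = followup_days if switch_day is None else min(followup_days, switch_day)
        disc_day = detect_discontinuation(
            episodes, scan_end, config.gap_threshold_days, config.gap_from
        )
        # time-to-event: discontinuation is the event; switch / follow-up end censor.
        if disc_day is not None and (switch_day is None or disc_day < switch_day):
            event_time, event = disc_day, True
        elif switch_day is not None:
            event_time, event = switch_day, False
        else:
            event_time, event = followup_days, False
        rows.append(
            {
                "patient_id": pid,
                "liver_status": m["liver_status"],
                "drug": index_drug,
                "index_date": index_date,
                "primary_nonadherent": primary_na,
                "followup_days": followup_days,
                "discontinuation_day": disc_day,
                "switch_day": switch_day,
                "status_6m": landmark_status(disc_day, switch_day, followup_days, config.window_6m_days),
                "status_12m": landmark_status(disc_day, switch_day, followup_days, config.window_12m_days),
                "event_time_days": event_time,
                "event_flag": event,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "liver_status", "drug", "index_date", "primary_nonadherent",
            "followup_days", "discontinuation_day", "switch_day", "status_6m",
            "status_12m", "event_time_days", "event_flag",
        ],
    )


def joint_classification(
    adherence_df: pd.DataFrame,
    persistence_df: pd.DataFrame,
    landmark: str = "12m",
) -> pd.DataFrame:
    """Joint adherence × persistence cells per drug × liver status.

    The denominator is the landmark-eligible population (follow-up ≥ landmark
    window, more than one class prescription), *including* switch-censored
    patients, so the four adherent/persistent cells plus censored categories
    partition each denominator. Percentages use that denominator.
    """
    status_col = f"status_{landmark}"
    adh = adherence_df[adherence_df["eligible"]][["patient_id", "drug", "liver_status", "adherent"]]
    per = persistence_df[~persistence_df["primary_nonadherent"]][
        ["patient_id", status_col]
    ]
    merged = adh.merge(per, on="patient_id", how="inner")
    merged = merged[merged[status_col] != "censored_followup"]
    rows = []
    for (drug, liver), sub in merged.groupby(["drug", "liver_status"]):
        n = len(sub)
        cells = {
            "adherent_persistent": ((sub["adherent"]) & (sub[status_col] == "persistent")).sum(),
            "adherent_nonpersistent": ((sub["adherent"]) & (sub[status_col] == "non_persistent")).sum(),
            "nonadherent_persistent": ((~sub["adherent"]) & (sub[status_col] == "persistent")).sum(),
            "nonadherent_nonpersistent": ((~sub["adherent"]) & (sub[status_col] == "non_persistent")).sum(),
            "censored_switch": (sub[status_col] == "censored_switch").sum(),
        }
        row = {"drug": drug, "liver_status": liver, "landmark": landmark, "n_eligible": n}
        for name, k in cells.items():
            row[name] = int(k)
            row[f"{name}_pct"] = round(100.0 * k / n, 1) if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
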