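"""Supply episodes, primary non-adherence, and PDC adherence at 6/12 months.

The supply model assumes each prescription issue provides 30 days of
medication unless the next issue arrives sooner, in which case the earlier
issue's duration is truncated to the inter-issue interval (no stockpiling).
Adherence is the proportion of days covered (PDC) over a fixed window after
the first prescription; a patient is adherent when PDC exceeds 0.80
(strictly). Patients with exactly one prescription of the class are primary
non-adherent and are excluded from PDC/persistence analyses, as are patients
with less follow-up than the window.

All interval arithmetic is on integer day offsets with half-open
``[start, end)`` episodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ehr_core import StudyConfig, drugs_of_class


@dataclass(frozen=True)
class SupplyEpisode:
    """A covered half-open interval [start, end) in day offsets."""

    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start


def build_supply_episodes(issue_days: Sequence[int], supply_days: int = 30) -> list[SupplyEpisode]:
    """Turn sorted issue-day offsets into non-overlapping supply episodes.

    Same-day duplicate issues collapse to one. Consecutive issues (d_i,
    d_{i+1}) yield an episode of duration min(supply_days, d_{i+1} - d_i);
    the final issue contributes the full assumed supply.
    """
    days = sorted(set(int(d) for d in issue_days))
    if not days:
        return []
    episodes = []
    for i, d in enumerate(days):
        if i + 1 < len(days):
            duration = min(supply_days, days[i + 1] - d)
        else:
            duration = supply_days
        episodes.append(SupplyEpisode(d, d + duration))
    return episodes


def covered_days(episodes: Sequence[SupplyEpisode], window_start: int, window_end: int) -> int:
    """Total covered days within the half-open window [window_start, window_end)."""
    total = 0
    for ep in episodes:
        total += max(0, min(ep.end, window_end) - max(ep.start, window_start))
    return total


def covered_days_grid(episodes: Sequence[SupplyEpisode], window_start: int, window_end: int) -> int:
    """Brute-force day-grid count of covered days (independent cross-check).

    Marks every covered day on a boolean array over the window; intended as
    the oracle the interval arithmetic must agree with.
    """
    n = window_end - window_start
    grid = np.zeros(n, dtype=bool)
    for ep in episodes:
        lo = max(ep.start, window_start) - window_start
        hi = min(ep.end, window_end) - window_start
        if hi > lo:
            grid[lo:hi] = True
    return int(grid.sum())


def classify_primary_nonadherence(n_class_issues: int) -> bool:
    """True iff the patient had exactly one prescription of the class.

    Zero prescriptions is outside this classification (the patient is
    unprescribed) and raises.
    """
    if n_class_issues < 1:
        raise ValueError("primary non-adherence is undefined for unprescribed patients")
    return n_class_issues == 1


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    drug: str
    window_days: int
    eligible: bool
    covered_days: float
    pdc: float  # NaN when ineligible
    adherent: bool


def pdc(
    episodes: Sequence[SupplyEpisode],
    index_day: int,
    window_days: int,
    followup_days: int,
    pdc_threshold: float = 0.80,
    *,
    patient_id: str = "",
    drug: str = "",
    primary_nonadherent: bool = False,
) -> AdherenceResult:
    """PDC over [index, index + window); adherent iff PDC > threshold.

    Eligibility requires follow-up of at least ``window_days`` from the index
    and more than one prescription (not primary non-adherent). Ineligible
    patients get ``pdc = NaN`` and ``adherent = False``.
    """
    eligible = followup_days >= window_days and not primary_nonadherent
    if not eligible:
        return AdherenceResult(patient_id, drug, window_days, False, float("nan"), float("nan"), False)
    if not episodes:
        raise ValueError("eligible patient must have at least one supply episode")
    cov = covered_days(episodes, index_day, index_day + window_days)
    value = cov / window_days
    return AdherenceResult(patient_id, drug, window_days, True, float(cov), value, value > pdc_threshold)


def compute_adherence(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: StudyConfig,
    window_days: int,
    level: str = "drug",
    switch_dates: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-patient adherence table for one cohort (one drug class).

    ``level='drug'`` computes PDC from the index drug's own issues (episodes
    truncated at an in-class switch when ``config.pdc_stop_at_switch``);
    ``level='class'`` uses the union of all same-class issues. Patients with
    no class prescription during follow-up are omitted (they are unexposed).

    Returns one row per prescribed member with the index drug/date, class
    issue count, primary non-adherence flag, eligibility, covered days, PDC
    and the adherent flag.
    """
    if level not in ("drug", "class"):
        raise ValueError("level must be 'drug' or 'class'")
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
        n_class = len(rx)
        primary_na = classify_primary_nonadherence(n_class)
        followup_days = int((m["followup_end"] - index_date).days)
        if level == "drug":
            sub = rx[rx["drug"] == index_drug]
        else:
            sub = rx
        issue_days = [(d - index_date).days for d in sub["issue_date"]]
        if level == "drug" and config.pdc_stop_at_switch:
            switch_date = None
            if switch_dates is not None and pid in switch_dates.index:
                switch_date = switch_dates.loc[pid]
            else:
                other = rx[rx["drug"] != index_drug]
                switch_date = other["issue_date"].min() if not other.empty else None
            if switch_date is not None and not pd.isna(switch_date):
                cut = (switch_date - index_date).days
                issue_days = [d for d in issue_days if d < cut]
        episodes = build_supply_episodes(issue_days, config.supply_days)
        res = pdc(
            episodes,
            0,
            window_days,
            followup_days,
            config.pdc_threshold,
            patient_id=pid,
            drug=index_drug,
            primary_nonadherent=primary_na,
        )
        rows.append(
            {
                "patient_id": pid,
                "liver_status": m["liver_status"],
                "drug": index_drug,
                "index_date": index_date,
                "n_class_issues": n_class,
                "primary_nonadherent": primary_na,
                "followup_days": followup_days,
                "window_days": window_days,
                "eligible": res.eligible,
                "covered_days": res.covered_days,
                "pdc": res.pdc,
                "adherent": res.adherent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "liver_status", "drug", "index_date", "n_class_issues",
            "primary_nonadherent", "followup_days", "window_days", "eligible",
            "covered_days", "pdc", "adherent",
        ],
    )
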