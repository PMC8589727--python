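"""Prescribing prevalence per 100 persons with normal-approximation CIs.

Prevalence is the proportion of cohort members (drug-naïve patients with a
qualifying indication) who receive at least one prescription of any drug in
the indicated class on or after the indication date. Confidence intervals are
Wald (central-limit-theorem) intervals for a binomial proportion, clipped to
[0, 100] and presented to one decimal with half-up rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .ehr_core import DrugClass, drugs_of_class


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (presentation only; internals stay exact)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion per 100 persons with its Wald interval."""

    k: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # k == 0 or k == n: zero-width interval

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(self.percent, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )


def wald_ci(k: int, n: int, z: float = 1.96) -> ProportionEstimate:
    """Wald interval for k successes of n, reported per 100 persons.

    p = k/n, half-width = z * sqrt(p(1-p)/n); bounds clipped to [0, 100].
    Degenerate cells (k = 0 or k = n) have zero-width intervals and are
    flagged.
    """
    if n <= 0:
        raise ValueError("wald_ci: denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("wald_ci: numerator must lie in [0, n]")
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return ProportionEstimate(
        k=k,
        n=n,
        percent=100.0 * p,
        ci_low=max(0.0, 100.0 * (p - half)),
        ci_high=min(100.0, 100.0 * (p + half)),
        degenerate=(k == 0 or k == n),
    )


def _prescribed_mask(members: pd.DataFrame, prescriptions: pd.DataFrame) -> pd.Series:
    """True where the member has ≥1 same-class prescription on/after indication."""
    flags = []
    rx_by_patient = dict(tuple(prescriptions.groupby("patient_id")))
    for _, m in members.iterrows():
        rx = rx_by_patient.get(m["patient_id"])
        if rx is None:
            flags.append(False)
            continue
        class_drugs = {d.value for d in drugs_of_class(m["indication_class"])}
        hit = rx[rx["drug"].isin(class_drugs) & (rx["issue_date"] >= m["indication_date"])]
        flags.append(not hit.empty)
    return pd.Series(flags, index=members.index, name="prescribed")


_STRATA = ("overall", "liver_status", "liver_subtype", "region")


def prevalence_table(
    members: pd.DataFrame,
    prescriptions: pd.DataFrame,
    by: tuple[str, ...] = _STRATA,
    z: float = 1.96,
) -> pd.DataFrame:
    """Prevalence estimates per stratum.

    Strata: ``overall``, ``liver_status``, ``liver_subtype`` (patients with
    several subtypes count in each), ``region``. Subtype numerators therefore
    need not sum to the liver-disease total.
    """
    unknown = set(by) - set(_STRATA)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}; expected subset of {_STRATA}")
    members = members.copy()
    members["prescribed"] = _prescribed_mask(members, prescriptions)

    rows = []

    def emit(stratum: str, level: str, sub: pd.DataFrame) -> None:
        if sub.empty:
            return
        est = wald_ci(int(sub["prescribed"].sum()), len(sub), z)
        pct, lo, hi = est.rounded()
        rows.append(
            {
                "stratum": stratum,
                "level": level,
                "k": est.k,
                "n": est.n,
                "percent": pct,
                "ci_low": lo,
                "ci_high": hi,
                "degenerate": est.degenerate,
            }
        )

    if "overall" in by:
        emit("overall", "all", members)
    if "liver_status" in by:
        for level, sub in members.groupby("liver_status"):
            emit("liver_status", level, sub)
    if "liver_subtype" in by:
        liver = members[members["liver_status"] == "with_liver_disease"]
        exploded = liver.assign(subtype=liver["liver_subtypes"].str.split(";")).explode("subtype")
        for level, sub in exploded[exploded["subtype"] != ""].groupby("subtype"):
            emit("liver_subtype", level, sub)
    if "region" in by:
        for level, sub in members.groupby("region"):
            emit("region", level, sub)
    return pd.DataFrame(rows)
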