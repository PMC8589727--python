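#!/usr/bin/env python
"""Severity and risk scoring at the index date, plus warfarin TTR.

Computes Child-Pugh class, FIB-4 stratum and CHA₂DS₂-VASc stratum for every
prescribed cohort member, and Rosendaal time-in-therapeutic-range (with the
60% cut) for warfarin users.
"""

import argparse
from pathlib import Path

import pandas as pd

from antithrombo.clinical_scores import score_cohort
from antithrombo.ehr_core import StudyConfig, read_table
from antithrombo.inr_ttr import compute_ttr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = StudyConfig()
    labs = read_table(args.data / "labs.csv", "labs")
    dx = read_table(args.data / "diagnoses.csv", "diagnoses")
    for cls in ("anticoagulant", "antiplatelet"):
        cohort = pd.read_csv(
            args.out / f"cohort_{cls}.csv", parse_dates=["indication_date", "followup_end"]
        )
        a12 = pd.read_csv(args.out / f"adherence_{cls}_12m.csv", parse_dates=["index_date"])
        scores = score_cohort(cohort, a12, labs, dx, study)
        scores.to_csv(args.out / f"scores_{cls}.csv", index=False)
        print(f"{cls}: scored {len(scores)} patients; "
              f"Child-Pugh classes {scores['child_pugh_class'].value_counts().to_dict()}")
        if cls == "anticoagulant":
            ttr = compute_ttr(a12, labs, study)
            ttr.to_csv(args.out / "ttr.csv", index=False)
            known = ttr.dropna(subset=["ttr_percent"])
            if len(known):
                print(f"  warfarin TTR: median {known['ttr_percent'].median():.1f}% "
                      f"({(known['above_cut'] == True).mean():.1%} above 60%) of {len(known)} users")


if __name__ == "__main__":
    main()
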