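#!/usr/bin/env python
"""Prescribing prevalence per 100 persons with Wald 95% CIs.

Computes prevalence overall and stratified by liver status, liver subtype
and region for each drug class, and prints the headline liver vs non-liver
contrast.
"""

import argparse
from pathlib import Path

import pandas as pd

from antithrombo.ehr_core import read_table
from antithrombo.prevalence_stats import prevalence_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rx = read_table(args.data / "prescriptions.csv", "prescriptions")
    for cls in ("anticoagulant", "antiplatelet"):
        cohort = pd.read_csv(
            args.out / f"cohort_{cls}.csv", parse_dates=["indication_date", "followup_end"]
        )
        tab = prevalence_table(cohort, rx)
        tab.to_csv(args.out / f"prevalence_{cls}.csv", index=False)
        liver = tab[(tab.stratum == "liver_status")].set_index("level")
        for status in ("with_liver_disease", "without_liver_disease"):
            if status in liver.index:
                r = liver.loc[status]
                print(f"{cls} / {status}: {r.percent}% [{r.k}/{r.n}] (CI {r.ci_low}-{r.ci_high})")


if __name__ == "__main__":
    main()
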