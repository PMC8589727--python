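#!/usr/bin/env python
"""Build the per-class new-user cohorts from the simulated tables.

Applies the denominator logic — prevalent liver disease, incident indication
strictly after the first liver diagnosis, age ≥ 30, drug-naïve filter,
follow-up resolution — and reports the resulting denominators.
"""

import argparse
from pathlib import Path

from antithrombo.cohort_builder import build_cohort
from antithrombo.ehr_core import StudyConfig, read_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = StudyConfig()
    patients = read_table(args.data / "patients.csv", "patients")
    diagnoses = read_table(args.data / "diagnoses.csv", "diagnoses")
    rx = read_table(args.data / "prescriptions.csv", "prescriptions")

    for cls in ("anticoagulant", "antiplatelet"):
        cohort = build_cohort(patients, diagnoses, rx, cls, study)
        out = args.out / f"cohort_{cls}.csv"
        cohort.to_csv(out, index=False)
        by = cohort["liver_status"].value_counts()
        print(f"{cls}: {len(cohort)} drug-naïve members "
              f"({by.get('with_liver_disease', 0)} liver / {by.get('without_liver_disease', 0)} non-liver) -> {out}")


if __name__ == "__main__":
    main()
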