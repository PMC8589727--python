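import itertools

import pandas as pd
import pytest

from antithrombo.cohort_builder import (
    apply_drug_naive_filter,
    build_cohort,
    classify_liver_status,
    find_incident_indication,
    resolve_followup_end,
)
from antithrombo.ehr_core import StudyConfig


def _dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "event_date", "condition", "source"])


def test_liver_status_multiple_subtypes():
    dx = _dx(
        [
            ("A", pd.Timestamp("2010-03-01"), "cirrhosis", "primary_care"),
            ("A", pd.Timestamp("2012-07-01"), "NAFLD", "primary_care"),
        ]
    )
    out = classify_liver_status(dx)
    assert out.loc["A", "liver_status"] == "with_liver_disease"
    assert out.loc["A", "liver_subtypes"] == "NAFLD;cirrhosis"
    assert out.loc["A", "liver_first_date"] == pd.Timestamp("2010-03-01")


def test_nonliver_conditions_do_not_classify():
    dx = _dx([("A", pd.Timestamp("2010-03-01"), "hypertension", "primary_care")])
    assert "A" not in classify_liver_status(dx).index


def test_indication_after_liver_diagnosis_qualifies():
    dx = _dx([("A", pd.Timestamp("2012-01-01"), "atrial_fibrillation", "secondary_care")])
    found = find_incident_indication(dx, pd.Timestamp("2010-01-01"), "anticoagulant")
    assert found == ("atrial_fibrillation", pd.Timestamp("2012-01-01"))


def test_indication_before_liver_diagnosis_excluded():
    dx = _dx([("A", pd.Timestamp("2008-01-01"), "atrial_fibrillation", "secondary_care")])
    assert find_incident_indication(dx, pd.Timestamp("2010-01-01"), "anticoagulant") is None


def test_same_day_indication_excluded_strict_after():
    dx = _dx([("A", pd.Timestamp("2010-01-01"), "atrial_fibrillation", "secondary_care")])
    assert find_incident_indication(dx, pd.Timestamp("2010-01-01"), "anticoagulant") is None


def test_earliest_antiplatelet_indication_wins():
    dx = _dx(
        [
            ("A", pd.Timestamp("2015-01-01"), "myocardial_infarction", "secondary_care"),
            ("A", pd.Timestamp("2013-01-01"), "transient_ischaemic_attack", "secondary_care"),
        ]
    )
    found = find_incident_indication(dx, pd.Timestamp("2011-01-01"), "antiplatelet")
    assert found == ("transient_ischaemic_attack", pd.Timestamp("2013-01-01"))


def test_followup_end_death_before_admin():
    patient = {
        "death_date": pd.Timestamp("2018-05-01"),
        "practice_last_collection": None,
        "registration_end": None,
    }
    date, reason = resolve_followup_end(patient, pd.Timestamp("2015-01-01"), StudyConfig())
    assert (date, reason) == (pd.Timestamp("2018-05-01"), "death")


def test_followup_end_defaults_to_admin_censor():
    patient = {"death_date": None, "practice_last_collection": None, "registration_end": None}
    date, reason = resolve_followup_end(patient, pd.Timestamp("2015-01-01"), StudyConfig())
    assert (date, reason) == (pd.Timestamp("2020-06-30"), "admin_censor")


def test_tie_break_priority_over_all_permutations():
    """On equal dates the reason follows endpoint > death > last_collection >
    deregistration > admin_censor, whatever the field order."""
    same = pd.Timestamp("2019-01-01")
    keys = ["death_date", "practice_last_collection", "registration_end"]
    for perm in itertools.permutations(keys):
        patient = {k: same for k in perm}
        _, reason = resolve_followup_end(patient, pd.Timestamp("2015-01-01"), StudyConfig())
        assert reason == "death"
    patient = {"death_date": None, "practice_last_collection": same, "registration_end": same}
    _, reason = resolve_followup_end(patient, pd.Timestamp("2015-01-01"), StudyConfig())
    assert reason == "last_collection"


def _members(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "indication_class", "indication_date"]
    )


def test_drug_naive_filter_is_class_specific():
    members = _members(
        [
            ("A", "anticoagulant", pd.Timestamp("2015-06-01")),
            ("B", "anticoagulant", pd.Timestamp("2015-06-01")),
        ]
    )
    rx = pd.DataFrame(
        [
            ("A", pd.Timestamp("2013-01-01"), "warfarin"),  # prior same-class: removed
            ("B", pd.Timestamp("2013-01-01"), "aspirin"),  # other class: kept
        ],
        columns=["patient_id", "issue_date", "drug"],
    )
    out = apply_drug_naive_filter(members, rx)
    assert list(out["patient_id"]) == ["B"]


def test_generated_cohort_matches_generator_bookkeeping(small_cohort, study):
    """Liver classification and the drug-naïve filter agree with the
    generator's internal truth records exactly."""
    truth = small_cohort.truth.set_index("patient_id")
    classified = classify_liver_status(small_cohort.diagnoses)
    assert set(classified.index) == set(truth.index[truth["liver"]])
    for cls in ("anticoagulant", "antiplatelet"):
        cohort = build_cohort(
            small_cohort.patients, small_cohort.diagnoses, small_cohort.prescriptions, cls, study
        )
        statuses = cohort.set_index("patient_id")["liver_status"]
        expect = truth.loc[statuses.index, "liver"].map(
            {True: "with_liver_disease", False: "without_liver_disease"}
        )
        assert (statuses == expect).all()


def test_liver_and_nonliver_partition_cohort(small_cohort, study):
    for cls in ("anticoagulant", "antiplatelet"):
        cohort = build_cohort(
            small_cohort.patients, small_cohort.diagnoses, small_cohort.prescriptions, cls, study
        )
        counts = cohort["liver_status"].value_counts()
        assert counts.sum() == len(cohort)


def test_planted_prior_exposure_is_removed_exactly():
    from antithrombo.synthetic_ehr import GeneratorConfig, generate_cohort

    syn = generate_cohort(GeneratorConfig(n_patients=500, seed=23, p_prior_exposure=0.10))
    study = StudyConfig()
    truth = syn.truth.set_index("patient_id")
    for cls in ("anticoagulant", "antiplatelet"):
        unfiltered = build_cohort(
            syn.patients, syn.diagnoses, syn.prescriptions, cls, study, drug_naive=False
        )
        filtered = apply_drug_naive_filter(unfiltered, syn.prescriptions)
        removed = set(unfiltered["patient_id"]) - set(filtered["patient_id"])
        planted = {
            pid
            for pid in unfiltered["patient_id"]
            if truth.at[pid, "prior_exposure"] and truth.at[pid, "drug_class"] == cls
        }
        assert removed == planted
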