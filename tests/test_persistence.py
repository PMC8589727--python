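import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from antithrombo import adherence as adh
from antithrombo import persistence as per
from antithrombo.adherence import build_supply_episodes
from antithrombo.cohort_builder import build_cohort
from antithrombo.ehr_core import StudyConfig
from antithrombo.persistence import detect_discontinuation, detect_switch, landmark_status
from antithrombo.synthetic_ehr import GeneratorConfig, generate_cohort

streams = st.lists(st.integers(0, 600), min_size=1, max_size=15).map(lambda xs: sorted(set(xs)))


def test_gap_after_last_supply_discontinues():
    """Issues at day 0 and 30 (supply to 60), nothing more, follow-up 400."""
    eps = build_supply_episodes([0, 30], 30)
    assert detect_discontinuation(eps, 400, 90) == 60


def test_seventy_day_gap_does_not_discontinue():
    eps = build_supply_episodes([0, 30, 130], 30)
    # gap from supply end (60) to next issue (130) is 70 < 90
    d = detect_discontinuation(eps, 1000, 90)
    assert d != 60
    assert d == 160  # the terminal gap after day-130 supply does qualify


def test_continuous_refills_never_discontinue():
    eps = build_supply_episodes(list(range(0, 400, 30)), 30)
    assert detect_discontinuation(eps, 400, 90) is None


def test_gap_comparison_is_inclusive():
    eps = build_supply_episodes([0], 30)
    assert detect_discontinuation(eps, 120, 90) == 30  # gap exactly 90
    assert detect_discontinuation(eps, 119, 90) is None


def test_issue_anchored_gap_variant():
    eps = build_supply_episodes([0], 30)
    # from the issue date a 90-day quiet period is reached at follow-up 90
    assert detect_discontinuation(eps, 90, 90, gap_from="issue") == 30
    assert detect_discontinuation(eps, 119, 90, gap_from="issue") == 30


def _rx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "issue_date", "drug"])


def test_switch_detection():
    rx = _rx([("A", pd.Timestamp("2010-01-01"), "warfarin"), ("A", pd.Timestamp("2010-03-12"), "rivaroxaban")])
    s = detect_switch(rx, "warfarin", pd.Timestamp("2010-01-01"), pd.Timestamp("2012-01-01"))
    assert s == pd.Timestamp("2010-03-12")


def test_no_switch_single_drug():
    rx = _rx([("A", pd.Timestamp("2010-01-01"), "warfarin")])
    assert detect_switch(rx, "warfarin", pd.Timestamp("2010-01-01"), pd.Timestamp("2012-01-01")) is None


def test_switch_outside_followup_ignored():
    rx = _rx(
        [
            ("A", pd.Timestamp("2010-01-01"), "aspirin"),
            ("A", pd.Timestamp("2011-02-05"), "clopidogrel"),  # day 400
        ]
    )
    fu = pd.Timestamp("2010-01-01") + pd.Timedelta(days=365)
    assert detect_switch(rx, "aspirin", pd.Timestamp("2010-01-01"), fu) is None


def test_landmark_statuses():
    assert landmark_status(60, None, 400, 183) == "non_persistent"
    assert landmark_status(None, 70, 400, 183) == "censored_switch"
    assert landmark_status(None, None, 400, 365) == "persistent"
    assert landmark_status(90, 70, 400, 183) == "censored_switch"  # switch first
    assert landmark_status(70, 70, 400, 183) == "censored_switch"  # same-day: switch dominates
    assert landmark_status(None, None, 100, 183) == "censored_followup"
    # events on/after the landmark leave the patient persistent at that landmark
    assert landmark_status(183, None, 400, 183) == "persistent"


@settings(max_examples=100, derandomize=True, deadline=None)
@given(streams, st.integers(60, 200), st.integers(0, 120))
def test_raising_gap_threshold_never_hastens_discontinuation(issues, thr, extra):
    eps = build_supply_episodes(issues, 30)
    lo = detect_discontinuation(eps, 800, thr)
    hi = detect_discontinuation(eps, 800, thr + extra)
    if hi is not None:
        assert lo is not None and lo <= hi


@pytest.fixture(scope="module")
def persistence_tables(small_cohort):
    study = StudyConfig()
    cohort = build_cohort(
        small_cohort.patients, small_cohort.diagnoses, small_cohort.prescriptions,
        "antiplatelet", study,
    )
    a6 = adh.compute_adherence(cohort, small_cohort.prescriptions, study, study.window_6m_days)
    a12 = adh.compute_adherence(cohort, small_cohort.prescriptions, study, study.window_12m_days)
    p = per.compute_persistence(cohort, small_cohort.prescriptions, study)
    return a6, a12, p


def test_persistence_monotone_from_6_to_12_months(persistence_tables):
    _, _, p = persistence_tables
    eligible6 = p[(p["followup_days"] >= 183) & ~p["primary_nonadherent"]]
    eligible12 = p[(p["followup_days"] >= 365) & ~p["primary_nonadherent"]]
    # on the common population, persistence cannot increase from 6 to 12 months
    common = eligible12["patient_id"]
    sub6 = eligible6[eligible6["patient_id"].isin(common)]
    prop6 = (sub6["status_6m"] == "persistent").mean()
    prop12 = (eligible12["status_12m"] == "persistent").mean()
    assert prop12 <= prop6 + 1e-12


@pytest.mark.parametrize("landmark", ["6m", "12m"])
def test_joint_cells_partition_eligible_denominator(persistence_tables, landmark):
    a6, a12, p = persistence_tables
    a = a6 if landmark == "6m" else a12
    jt = per.joint_classification(a, p, landmark)
    assert not jt.empty
    cells = [
        "adherent_persistent", "adherent_nonpersistent",
        "nonadherent_persistent", "nonadherent_nonpersistent", "censored_switch",
    ]
    assert (jt[cells].sum(axis=1) == jt["n_eligible"]).all()


def test_early_discontinuers_are_mostly_nonpersistent():
    gen = GeneratorConfig(
        n_patients=400, seed=5, archetype_weights=(0.0, 0.0, 0.0, 1.0),
        early_mean_refills=1.5, switch_probability=0.0,
    )
    syn = generate_cohort(gen)
    study = StudyConfig()
    for cls in ("anticoagulant", "antiplatelet"):
        cohort = build_cohort(syn.patients, syn.diagnoses, syn.prescriptions, cls, study)
        p = per.compute_persistence(cohort, syn.prescriptions, study)
        e = p[(p["followup_days"] >= 365) & ~p["primary_nonadherent"]]
        if len(e) >= 20:
            assert (e["status_12m"] == "non_persistent").mean() > 0.8
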