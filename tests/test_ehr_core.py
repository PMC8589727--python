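import datetime as dt

import pandas as pd
import pytest

from antithrombo.ehr_core import (
    ANTICOAGULANTS,
    ANTIPLATELETS,
    RowValidationError,
    SchemaError,
    StudyConfig,
    drug_class,
    read_table,
    validate_table,
    write_table,
)


def test_drug_class_is_total_function_with_five_per_class():
    assert len(ANTICOAGULANTS) == 5 and len(ANTIPLATELETS) == 5
    assert drug_class("warfarin").value == "anticoagulant"
    assert drug_class("clopidogrel").value == "antiplatelet"
    for d in ANTICOAGULANTS | ANTIPLATELETS:
        assert drug_class(d).value in ("anticoagulant", "antiplatelet")


def test_read_well_formed_prescriptions(tmp_path):
    p = tmp_path / "rx.csv"
    p.write_text(
        "patient_id,issue_date,drug\n"
        "A,2015-01-01,warfarin\nA,2015-01-20,warfarin\nB,2016-05-05,aspirin\n"
    )
    df = read_table(p, "prescriptions")
    assert len(df) == 3
    assert df["issue_date"].iloc[0] == pd.Timestamp("2015-01-01")
    assert list(df["drug"]) == ["warfarin", "warfarin", "aspirin"]


def test_bad_enum_value_reports_row(tmp_path):
    p = tmp_path / "rx.csv"
    p.write_text("patient_id,issue_date,drug\nA,2015-01-01,warfarin\nA,2015-02-01,warfarinn\n")
    with pytest.raises(RowValidationError) as exc:
        read_table(p, "prescriptions")
    assert 1 in exc.value.rows


def test_missing_column_names_it():
    with pytest.raises(SchemaError, match="drug"):
        validate_table(pd.DataFrame({"patient_id": ["A"], "issue_date": ["2015-01-01"]}), "prescriptions")


def test_duplicate_prescriptions_are_retained(tmp_path):
    p = tmp_path / "rx.csv"
    p.write_text("patient_id,issue_date,drug\nA,2015-01-01,warfarin\nA,2015-01-01,warfarin\n")
    assert len(read_table(p, "prescriptions")) == 2


def test_null_death_date_round_trips(tmp_path):
    df = pd.DataFrame(
        {
            "patient_id": ["A"],
            "sex": ["male"],
            "birth_year": [1950],
            "region": ["London"],
            "registration_start": ["2000-01-01"],
            "registration_end": [None],
            "death_date": [None],
            "practice_last_collection": [None],
        }
    )
    path = tmp_path / "patients.csv"
    write_table(df, path, "patients")
    back = read_table(path, "patients")
    assert pd.isna(back["death_date"].iloc[0])
    assert back["birth_year"].iloc[0] == 1950


def test_empty_table_writes_header_only(tmp_path):
    df = pd.DataFrame(columns=["patient_id", "issue_date", "drug"])
    path = tmp_path / "rx.csv"
    write_table(df, path, "prescriptions")
    assert path.read_text().strip() == "patient_id,issue_date,drug"
    assert read_table(path, "prescriptions").empty


def test_registration_order_invariant_rejected():
    df = pd.DataFrame(
        {
            "patient_id": ["A"],
            "sex": ["male"],
            "birth_year": [1950],
            "region": ["London"],
            "registration_start": ["2010-01-01"],
            "registration_end": ["2005-01-01"],
            "death_date": [None],
            "practice_last_collection": [None],
        }
    )
    with pytest.raises(RowValidationError):
        validate_table(df, "patients")


def test_lab_value_invariants():
    bad = pd.DataFrame(
        {"patient_id": ["A"], "date": ["2010-01-01"], "analyte": ["INR"], "value": [25.0]}
    )
    with pytest.raises(RowValidationError):
        validate_table(bad, "labs")


@pytest.mark.parametrize("kind", ["patients", "prescriptions", "diagnoses", "labs"])
def test_round_trip_identity_on_generated_tables(tmp_path, small_cohort, kind):
    """read(write(x)) == x for every table kind, field by field."""
    df = getattr(small_cohort, kind)
    path = tmp_path / f"{kind}.csv"
    write_table(df, path, kind)
    back = read_table(path, kind)
    ref = df.reset_index(drop=True)
    pd.testing.assert_frame_equal(back, ref[back.columns], check_dtype=False)


def test_study_config_validation_and_yaml(tmp_path):
    cfg = StudyConfig(supply_days=30, gap_threshold_days=90)
    path = tmp_path / "study.yaml"
    cfg.to_yaml(path)
    assert StudyConfig.from_yaml(path) == cfg
    with pytest.raises(ValueError):
        StudyConfig(supply_days=90, gap_threshold_days=90)
    with pytest.raises(ValueError):
        StudyConfig(pdc_threshold=1.2)
    assert cfg.admin_censor_date == dt.date(2020, 6, 30)
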