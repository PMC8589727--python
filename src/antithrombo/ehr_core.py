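"""Domain types, closed enumerations and validated CSV I/O for the four linked EHR tables.

The analysis operates on four longitudinal tables keyed by an opaque
``patient_id``:

* ``patients``       — demographics and registration/censoring anchors
* ``prescriptions``  — dated issues of one of ten antithrombotic drugs
* ``diagnoses``      — dated condition events from primary or secondary care
* ``labs``           — dated laboratory measurements (fixed unit per analyte)

Tables are carried as pandas DataFrames validated against the schemas below.
All dates are calendar dates (day resolution, stored as ISO-8601 in CSV);
interval arithmetic throughout the package uses integer day offsets with
half-open ``[start, end)`` conventions.
"""

from __future__ import annotations

import datetime as _dt
import enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator


class SchemaError(ValueError):
    """A table is structurally wrong (missing/extra column, wrong kind)."""


class RowValidationError(ValueError):
    """One or more rows violate a field invariant; carries the row indices."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {list(rows)[:10]}{'…' if len(rows) > 10 else ''})")
        self.rows = list(rows)


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class DrugClass(str, enum.Enum):
    anticoagulant = "anticoagulant"
    antiplatelet = "antiplatelet"


class Drug(str, enum.Enum):
    # anticoagulants
    apixaban = "apixaban"
    dabigatran = "dabigatran"
    edoxaban = "edoxaban"
    rivaroxaban = "rivaroxaban"
    warfarin = "warfarin"
    # antiplatelets
    aspirin = "aspirin"
    clopidogrel = "clopidogrel"
    dipyridamole = "dipyridamole"
    prasugrel = "prasugrel"
    ticagrelor = "ticagrelor"


ANTICOAGULANTS = frozenset(
    {Drug.apixaban, Drug.dabigatran, Drug.edoxaban, Drug.rivaroxaban, Drug.warfarin}
)
ANTIPLATELETS = frozenset(
    {Drug.aspirin, Drug.clopidogrel, Drug.dipyridamole, Drug.prasugrel, Drug.ticagrelor}
)

_CLASS_OF_DRUG: Mapping[Drug, DrugClass] = {
    **{d: DrugClass.anticoagulant for d in ANTICOAGULANTS},
    **{d: DrugClass.antiplatelet for d in ANTIPLATELETS},
}


def drug_class(drug: Drug | str) -> DrugClass:
    """The therapeutic class of a drug (5 anticoagulants, 5 antiplatelets)."""
    return _CLASS_OF_DRUG[Drug(drug)]


def drugs_of_class(cls: DrugClass | str) -> frozenset[Drug]:
    cls = DrugClass(cls)
    return ANTICOAGULANTS if cls is DrugClass.anticoagulant else ANTIPLATELETS


class Condition(str, enum.Enum):
    # six chronic liver diseases
    ALD = "ALD"
    autoimmune_liver_disease = "autoimmune_liver_disease"
    cirrhosis = "cirrhosis"
    HBV = "HBV"
    HCV = "HCV"
    NAFLD = "NAFLD"
    # cardiovascular indications
    atrial_fibrillation = "atrial_fibrillation"
    myocardial_infarction = "myocardial_infarction"
    peripheral_arterial_disease = "peripheral_arterial_disease"
    unstable_angina = "unstable_angina"
    transient_ischaemic_attack = "transient_ischaemic_attack"
    # comorbidities / severity markers
    chronic_kidney_disease = "chronic_kidney_disease"
    ascites = "ascites"
    hepatic_encephalopathy = "hepatic_encephalopathy"
    varices = "varices"
    heart_failure = "heart_failure"
    hypertension = "hypertension"
    diabetes = "diabetes"
    stroke_ischaemic = "stroke_ischaemic"
    bleeding_nonfatal = "bleeding_nonfatal"
    vascular_disease = "vascular_disease"
    proton_pump_inhibitor_use = "proton_pump_inhibitor_use"


LIVER_CONDITIONS = frozenset(
    {
        Condition.ALD,
        Condition.autoimmune_liver_disease,
        Condition.cirrhosis,
        Condition.HBV,
        Condition.HCV,
        Condition.NAFLD,
    }
)

#: Incident indications per drug class: atrial fibrillation indicates
#: anticoagulation; MI / PAD / unstable angina / TIA indicate antiplatelets.
INDICATIONS: Mapping[DrugClass, frozenset[Condition]] = {
    DrugClass.anticoagulant: frozenset({Condition.atrial_fibrillation}),
    DrugClass.antiplatelet: frozenset(
        {
            Condition.myocardial_infarction,
            Condition.peripheral_arterial_disease,
            Condition.unstable_angina,
            Condition.transient_ischaemic_attack,
        }
    ),
}


class Source(str, enum.Enum):
    primary_care = "primary_care"
    secondary_care = "secondary_care"


class Analyte(str, enum.Enum):
    """Lab analytes with a fixed unit each (declared here, not per row)."""

    INR = "INR"  # dimensionless ratio
    bilirubin_total = "bilirubin_total"  # mg/dL
    albumin = "albumin"  # g/dL
    AST = "AST"  # U/L
    ALT = "ALT"  # U/L
    platelets = "platelets"  # 10^9/L


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

TABLE_KINDS = ("patients", "prescriptions", "diagnoses", "labs")

#: column name -> ("date" | "str" | "int" | "float" | enum class, nullable)
SCHEMAS: Mapping[str, Mapping[str, tuple] ] = {
    "patients": {
        "patient_id": ("str", False),
        "sex": (Sex, False),
        "birth_year": ("int", False),
        "region": ("str", False),
        "registration_start": ("date", False),
        "registration_end": ("date", True),
        "death_date": ("date", True),
        "practice_last_collection": ("date", True),
    },
    "prescriptions": {
        "patient_id": ("str", False),
        "issue_date": ("date", False),
        "drug": (Drug, False),
    },
    "diagnoses": {
        "patient_id": ("str", False),
        "event_date": ("date", False),
        "condition": (Condition, False),
        "source": (Source, False),
    },
    "labs": {
        "patient_id": ("str", False),
        "date": ("date", False),
        "analyte": (Analyte, False),
        "value": ("float", False),
    },
}


def _parse_dates(s: pd.Series, col: str) -> pd.Series:
    parsed = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
    bad = s.notna() & (s.astype(str).str.len() > 0) & parsed.isna()
    if bad.any():
        raise RowValidationError(f"unparsable ISO-8601 date in column '{col}'", s.index[bad])
    return parsed


def validate_table(df: pd.DataFrame, table_kind: str) -> pd.DataFrame:
    """Validate (and normalise dtypes of) a table against its schema.

    Returns a copy with date columns as ``datetime64[ns]`` and enum columns as
    plain strings drawn from the closed enumerations. Raises
    :class:`SchemaError` for structural problems and
    :class:`RowValidationError` (with row indices) for value-level problems.
    """
    if table_kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    schema = SCHEMAS[table_kind]
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"{table_kind}: missing column '{col}'")
    out = df.loc[:, list(schema)].copy()
    for col, (kind, nullable) in schema.items():
        s = out[col]
        if not nullable:
            null = s.isna()
            if null.any():
                raise RowValidationError(f"{table_kind}.{col}: null in non-nullable column", s.index[null])
        if kind == "date":
            if not pd.api.types.is_datetime64_any_dtype(s):
                s = _parse_dates(s.replace("", pd.NA), col)
            out[col] = s
        elif kind == "int":
            out[col] = s.astype("int64")
        elif kind == "float":
            out[col] = s.astype("float64")
        elif kind == "str":
            out[col] = s.astype(str)
        elif isinstance(kind, type) and issubclass(kind, enum.Enum):
            allowed = {e.value for e in kind}
            vals = s.astype(str)
            bad = ~vals.isin(allowed)
            if bad.any():
                raise RowValidationError(
                    f"{table_kind}.{col}: value not in {sorted(allowed)}", s.index[bad]
                )
            out[col] = vals
    _check_invariants(out, table_kind)
    return out


def _check_invariants(df: pd.DataFrame, table_kind: str) -> None:
    if table_kind == "patients":
        ends = df[["registration_end", "death_date", "practice_last_collection"]].min(axis=1)
        bad = ends.notna() & (df["registration_start"] >= ends)
        if bad.any():
            raise RowValidationError(
                "patients: registration_start must precede every end/censoring anchor",
                df.index[bad],
            )
    elif table_kind == "labs":
        bad = ~(df["value"] > 0)
        if bad.any():
            raise RowValidationError("labs: value must be > 0", df.index[bad])
        inr = df["analyte"] == Analyte.INR.value
        bad = inr & ~df["value"].between(0.5, 20.0, inclusive="neither")
        if bad.any():
            raise RowValidationError("labs: INR must lie in (0.5, 20)", df.index[bad])


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read and validate one of the four EHR tables from CSV.

    Row order is preserved; duplicate (patient_id, issue_date, drug)
    prescriptions are retained — re-issues are legitimate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return validate_table(df, table_kind)


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a validated table as CSV: ISO-8601 dates, stable column order.

    ``read_table(write_table(x))`` round-trips losslessly; null dates become
    empty fields.
    """
    df = validate_table(df, table_kind)
    out = df.copy()
    for col, (kind, _) in SCHEMAS[table_kind].items():
        if kind == "date":
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def add_drug_class(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``drug_class`` column derived from ``drug``."""
    out = prescriptions.copy()
    out["drug_class"] = out["drug"].map(lambda d: drug_class(d).value)
    return out


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


class StudyConfig(BaseModel):
    """Every tunable analysis rule in one validated object.

    Defaults encode the study conventions: 30-day assumed supply, 90-day
    discontinuation gap, PDC > 0.80 adherence cut, 183/365-day landmark
    windows, z = 1.96 Wald intervals, TTR > 60% covariate cut, and
    administrative censoring at the end of June 2020.
    """

    study_start: _dt.date = _dt.date(1998, 1, 1)
    admin_censor_date: _dt.date = _dt.date(2020, 6, 30)
    supply_days: int = Field(30, gt=0)
    gap_threshold_days: int = Field(90, gt=0)
    pdc_threshold: float = Field(0.80, gt=0, lt=1)
    window_6m_days: int = Field(183, gt=0)
    window_12m_days: int = Field(365, gt=0)
    ci_z: float = Field(1.96, gt=0)
    ttr_cut: float = Field(60.0, ge=0, le=100)
    min_age: int = Field(30, ge=0)
    lab_lookback_days: int = Field(365, gt=0)
    lab_lookahead_days: int = Field(30, ge=0)
    gap_from: str = Field("supply_end", pattern="^(supply_end|issue)$")
    pdc_stop_at_switch: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _cross_field(self) -> "StudyConfig":
        if self.gap_threshold_days <= self.supply_days:
            raise ValueError("gap_threshold_days must exceed supply_days")
        if self.admin_censor_date <= self.study_start:
            raise ValueError("admin_censor_date must follow study_start")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
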