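"""Core claims data model and study configuration.

The pipeline operates on three patient-level claims tables — patients,
diagnoses, prescriptions — joined on an opaque ``patient_id``, mirroring the
structure of hospital claims databases (diagnoses carry ICD-10 codes and a
care setting; dispensing events carry a product code, days supplied and a
daily pill count).  All records use calendar dates externally; coverage
arithmetic converts them to integer day offsets from the per-patient index
date, with every window half-open ``[start, start + length)``.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

Setting = Literal["inpatient", "outpatient"]
Sex = Literal["male", "female"]

#: Default enrollment window of the emulated study (first qualifying
#: outpatient antihypertensive prescription must fall inside it).
DEFAULT_INDEX_PERIOD = (dt.date(2014, 4, 1), dt.date(2015, 3, 31))

#: ICD-10 code prefix identifying essential (primary) hypertension.
HYPERTENSION_ICD10_PREFIX = "I10"

DEFAULT_COMORBIDITY_CODES: dict[str, list[str]] = {
    "diabetes": ["E10", "E11", "E12", "E13", "E14"],
    "dyslipidemia": ["E78"],
    "gout_hyperuricemia": ["E79", "M10"],
    "renal_disease": ["N18", "N19"],
    "heart_disease": ["I20", "I21", "I22", "I23", "I24", "I25", "I50"],
    "cerebrovascular_disease": [f"I6{i}" for i in range(10)],
}


class DiagnosisClaim(BaseModel):
    """A single diagnosis record: ICD-10 code, date and care setting."""

    patient_id: str
    code: str = Field(min_length=1)
    date: dt.date
    setting: Setting


class Prescription(BaseModel):
    """One dispensing event.

    ``days_supplied`` is the number of calendar days the dispensed quantity
    covers at the prescribed daily dose; ``pills_per_day`` the number of
    tablets taken per day (several antihypertensives are dosed twice daily).
    """

    patient_id: str
    product_code: str = Field(min_length=1)
    date: dt.date
    days_supplied: int = Field(ge=1)
    pills_per_day: float = Field(gt=0)
    setting: Setting


class PatientRecord(BaseModel):
    """A patient with demographics plus all their claims."""

    patient_id: str
    sex: Sex
    birth_year_month: str = Field(pattern=r"^\d{4}-\d{2}$")
    diagnoses: list[DiagnosisClaim] = Field(default_factory=list)
    prescriptions: list[Prescription] = Field(default_factory=list)

    @model_validator(mode="after")
    def _children_match_patient(self) -> "PatientRecord":
        for rec in (*self.diagnoses, *self.prescriptions):
            if rec.patient_id != self.patient_id:
                raise ValueError(
                    f"child record patient_id {rec.patient_id!r} does not "
                    f"match {self.patient_id!r}"
                )
        return self

    def age_at(self, date: dt.date) -> int:
        """Age in completed years, taking birth day as day 1 of the month.

        Claims databases typically store year/month of birth only.
        """
        year, month = (int(x) for x in self.birth_year_month.split("-"))
        age = date.year - year
        if (date.month, date.day) < (month, 1):
            age -= 1
        return age


class ClaimsDataset(BaseModel):
    """An in-memory claims database: one :class:`PatientRecord` per patient."""

    patients: list[PatientRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _ids_unique(self) -> "ClaimsDataset":
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterable[PatientRecord]:  # type: ignore[override]
        return iter(self.patients)

    def get(self, patient_id: str) -> Optional[PatientRecord]:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        return None


class StudyConfig(BaseModel):
    """All tunable study parameters, with the emulated study's defaults.

    ``pdc_category_bounds`` is ``(high_threshold, low_threshold)`` as
    fractions: PDC >= high_threshold is "high", PDC < low_threshold is
    "low", anything between is "intermediate".
    """

    index_period: tuple[dt.date, dt.date] = DEFAULT_INDEX_PERIOD
    lookback_days: int = Field(default=365, gt=0)
    followup_days: int = Field(default=365, gt=0)
    min_age_years: int = Field(default=20, ge=0)
    pdc_category_bounds: tuple[float, float] = (0.80, 0.40)
    overlap_policy: Literal["UNION", "SHIFT_FORWARD"] = "UNION"
    regimen_pdc_mode: Literal["ANY", "ALL"] = "ANY"
    persistence_window_days: int = Field(default=91, gt=0)
    persistence_anchor: Literal["followup", "calendar"] = "followup"
    comorbidity_codes: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COMORBIDITY_CODES.items()}
    )
    inpatient_supply_counts: bool = True
    drug_count_basis: Literal["ingredients", "products"] = "ingredients"
    equal_variance_ttest: bool = False
    random_seed: int = 0

    @field_validator("index_period")
    @classmethod
    def _period_ordered(cls, v: tuple[dt.date, dt.date]) -> tuple[dt.date, dt.date]:
        if v[0] > v[1]:
            raise ValueError("index_period start must not be after end")
        return v

    @field_validator("pdc_category_bounds")
    @classmethod
    def _bounds_ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        high, low = v
        if not (0.0 < low < high < 1.0):
            raise ValueError(
                "pdc_category_bounds must be (high, low) with 0 < low < high < 1; "
                f"got {v}"
            )
        return v

    @property
    def high_bound(self) -> float:
        return self.pdc_category_bounds[0]

    @property
    def low_bound(self) -> float:
        return self.pdc_category_bounds[1]
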