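"""Cohort selection: index dates, selection/exclusion criteria, attrition.

The analysis cohort consists of hypertensive outpatients with a qualifying
index prescription, applying the criteria in a fixed order and attributing
each exclusion to the first criterion that fails:

1. ``hypertension_diagnosis`` — at least one outpatient diagnosis with ICD-10
   prefix I10 (essential hypertension).
2. ``index_prescription`` — an outpatient antihypertensive prescription
   within the enrollment (index) period; the earliest such date is the
   patient's index date.
3. ``age_ge_min`` — at least ``min_age_years`` (default 20) on the index date.
4. ``lookback_claim`` — at least one claim of any kind (diagnosis or
   prescription) in the look-back window ``[index - lookback_days, index)``.
5. ``quarterly_persistence`` — at least one antihypertensive prescription in
   every consecutive ~3-month sub-window of the follow-up.
6. ``not_loop_aldosterone_only`` — the index-date regimen is not composed
   solely of loop diuretics and/or aldosterone antagonists.

Permuting the criteria changes only the attribution of exclusions, never
the final included set.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import (
    HYPERTENSION_ICD10_PREFIX,
    ClaimsDataset,
    PatientRecord,
    Prescription,
    StudyConfig,
)
from .ontology import DrugOntology, DrugProduct, is_excluded_only_regimen

CRITERIA_ORDER = [
    "hypertension_diagnosis",
    "index_prescription",
    "age_ge_min",
    "lookback_claim",
    "quarterly_persistence",
    "not_loop_aldosterone_only",
]


@dataclass
class AttritionStep:
    criterion: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class CohortResult:
    """Included patients with index dates, plus the per-criterion attrition."""

    included: list[tuple[str, dt.date]]
    attrition: list[AttritionStep] = field(default_factory=list)

    @property
    def index_dates(self) -> dict[str, dt.date]:
        return dict(self.included)

    def attrition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.criterion, s.n_before, s.n_excluded, s.n_after) for s in self.attrition],
            columns=["criterion", "n_before", "n_excluded", "n_after"],
        )

    def cohort_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.included, columns=["patient_id", "index_date"])


def _is_antihypertensive(rx: Prescription, ontology: DrugOntology, strict: bool) -> bool:
    if rx.product_code in ontology:
        return True
    if strict:
        from .ontology import OntologyError

        raise OntologyError(
            f"patient {rx.patient_id}: unknown product code {rx.product_code!r}"
        )
    return False


def determine_index_date(
    patient: PatientRecord,
    config: StudyConfig,
    ontology: DrugOntology,
    strict: bool = True,
) -> Optional[dt.date]:
    """Date of the first outpatient antihypertensive prescription inside the
    index period, or None."""
    start, end = config.index_period
    dates = [
        rx.date
        for rx in patient.prescriptions
        if rx.setting == "outpatient"
        and start <= rx.date <= end
        and _is_antihypertensive(rx, ontology, strict)
    ]
    return min(dates) if dates else None


def persistence_windows(followup_days: int, window_days: int) -> list[tuple[int, int]]:
    """Partition ``[0, followup_days)`` into consecutive windows of
    ``window_days`` with the last window absorbing the remainder
    (91/91/91/92 for a 365-day follow-up)."""
    n = max(followup_days // window_days, 1)
    bounds = [i * window_days for i in range(n)] + [followup_days]
    return [(bounds[i], bounds[i + 1]) for i in range(n)]


def check_quarterly_persistence(
    prescriptions: Sequence[Prescription],
    index_date: dt.date,
    config: StudyConfig,
    ontology: Optional[DrugOntology] = None,
    strict: bool = True,
) -> bool:
    """True iff every persistence sub-window of the follow-up contains at
    least one antihypertensive prescription date.

    With ``persistence_anchor="followup"`` (default) sub-windows are anchored
    at the patient's own index date; ``"calendar"`` anchors them at the start
    of the study index period instead, checking only windows that overlap
    the patient's observation.
    """
    offsets = sorted(
        (rx.date - index_date).days
        for rx in prescriptions
        if ontology is None or _is_antihypertensive(rx, ontology, strict)
    )
    if config.persistence_anchor == "followup":
        windows = persistence_windows(config.followup_days, config.persistence_window_days)
    else:
        period_start, period_end = config.index_period
        span = (period_end - period_start).days + 1
        shift = (period_start - index_date).days
        windows = [
            (lo + shift, hi + shift)
            for lo, hi in persistence_windows(span, config.persistence_window_days)
            if hi + shift > 0  # windows entirely before the index date can't apply
        ]
    day_set = set(offsets)
    return all(any(lo <= d < hi for d in day_set) for lo, hi in windows)


def index_regimen_products(
    patient: PatientRecord,
    index_date: dt.date,
    ontology: DrugOntology,
    strict: bool = True,
) -> list[DrugProduct]:
    """Ontology products dispensed as outpatient on the index date."""
    products = []
    for rx in patient.prescriptions:
        if rx.date == index_date and rx.setting == "outpatient":
            if _is_antihypertensive(rx, ontology, strict):
                products.append(ontology[rx.product_code])
    return products


def evaluate_criteria(
    patient: PatientRecord,
    config: StudyConfig,
    ontology: DrugOntology,
    strict: bool = True,
) -> tuple[dict[str, bool], Optional[dt.date]]:
    """Evaluate every selection criterion independently.

    Criteria that require an index date fail when none can be determined.
    Returns (criterion -> passed, index_date).
    """
    index_date = determine_index_date(patient, config, ontology, strict)
    results: dict[str, bool] = {}
    results["hypertension_diagnosis"] = any(
        d.code.startswith(HYPERTENSION_ICD10_PREFIX) and d.setting == "outpatient"
        for d in patient.diagnoses
    )
    results["index_prescription"] = index_date is not None
    if index_date is None:
        for crit in CRITERIA_ORDER[2:]:
            results[crit] = False
        return results, None

    results["age_ge_min"] = patient.age_at(index_date) >= config.min_age_years
    lb_start = index_date - dt.timedelta(days=config.lookback_days)
    results["lookback_claim"] = any(
        lb_start <= rec.date < index_date
        for rec in (*patient.diagnoses, *patient.prescriptions)
    )
    results["quarterly_persistence"] = check_quarterly_persistence(
        patient.prescriptions, index_date, config, ontology, strict
    )
    products = index_regimen_products(patient, index_date, ontology, strict)
    results["not_loop_aldosterone_only"] = bool(products) and not is_excluded_only_regimen(
        products
    )
    return results, index_date


def apply_selection(
    dataset: ClaimsDataset,
    config: StudyConfig,
    ontology: DrugOntology,
    strict: bool = True,
    criteria_order: Optional[Sequence[str]] = None,
) -> CohortResult:
    """Apply all selection criteria in order and build the attrition table.

    Each excluded patient is attributed to the first criterion in
    ``criteria_order`` (default :data:`CRITERIA_ORDER`) that they fail.
    """
    order = list(criteria_order) if criteria_order is not None else list(CRITERIA_ORDER)
    if set(order) != set(CRITERIA_ORDER):
        raise ValueError(f"criteria_order must be a permutation of {CRITERIA_ORDER}")

    evaluated = {
        p.patient_id: evaluate_criteria(p, config, ontology, strict) for p in dataset
    }
    remaining = [p.patient_id for p in dataset]
    attrition: list[AttritionStep] = []
    for crit in order:
        survivors = [pid for pid in remaining if evaluated[pid][0][crit]]
        attrition.append(
            AttritionStep(
                criterion=crit,
                n_before=len(remaining),
                n_excluded=len(remaining) - len(survivors),
                n_after=len(survivors),
            )
        )
        remaining = survivors

    included = [(pid, evaluated[pid][1]) for pid in remaining]
    assert all(d is not None for _, d in included)
    return CohortResult(included=included, attrition=attrition)  # type: ignore[arg-type]
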