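"""Synthetic claims generator.

Emulates the structure of a hospital claims extract for hypertensive
outpatients: every generated patient has an index prescription of an
antihypertensive regimen inside the enrollment period, refill behaviour
drawn from an adherence stratum, 1-4 look-back prescriptions, an outpatient
hypertension diagnosis, and comorbidity diagnosis codes at configured
prevalences.  A ground-truth table records each patient's stratum, regimen
and expected long-run coverage so downstream stages can be tested against
known answers.

Refill model: a patient refills ``days_supplied + gap`` days after each
dispensing, where the gap is a non-negative integer draw with configurable
mean and dispersion (negative-binomial shaped; dispersion 0 degenerates to
a constant gap).  With no discontinuation the long-run fraction of days
covered is ``days_supplied / (days_supplied + gap_mean)`` — the closed form
used by parameter-recovery tests.  Over a finite window anchored at the
first fill the realized mean PDC slightly exceeds this limit (start-up and
truncation effects of the renewal process), so recovery tests measure over
long horizons.

Violation injection mutates compliant patients minimally so that each
flagged patient violates exactly one named selection criterion, making the
cohort attrition table exactly predictable from the truth table.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .model import (
    DEFAULT_INDEX_PERIOD,
    HYPERTENSION_ICD10_PREFIX,
    ClaimsDataset,
    DiagnosisClaim,
    PatientRecord,
    Prescription,
    StudyConfig,
)
from .ontology import DrugClass, DrugOntology, DrugProduct, default_ontology

#: Criteria that can be deliberately violated, in canonical order.
VIOLATION_CRITERIA = [
    "hypertension_diagnosis",
    "index_prescription",
    "age_ge_min",
    "lookback_claim",
    "quarterly_persistence",
    "not_loop_aldosterone_only",
]

_COMORBIDITY_DEFAULT_CODE = {
    "diabetes": "E11",
    "dyslipidemia": "E78",
    "gout_hyperuricemia": "E79",
    "renal_disease": "N18",
    "heart_disease": "I50",
    "cerebrovascular_disease": "I63",
}


class AdherenceProfile(BaseModel):
    """One refill-behaviour stratum.

    ``refill_gap_dispersion`` scales overdispersion of the gap draw
    (variance = mean + dispersion * mean^2); 0 yields a constant gap.
    """

    name: str
    refill_gap_mean: float = Field(ge=0)
    refill_gap_dispersion: float = Field(ge=0)
    discontinue_prob_per_refill: float = Field(ge=0, le=1, default=0.0)

    def expected_coverage(self, days_supplied: int) -> float:
        """Long-run covered fraction for an uninterrupted refill sequence."""
        return days_supplied / (days_supplied + self.refill_gap_mean)


class RegimenMenuEntry(BaseModel):
    """One index-regimen option: a class combination with FDC usage rates."""

    weight: float = Field(gt=0)
    classes: list[DrugClass] = Field(min_length=1)
    p_fdc: float = Field(ge=0, le=1, default=0.0)
    p_redundant_given_fdc: float = Field(ge=0, le=1, default=0.0)


def default_strata() -> list[tuple[float, AdherenceProfile]]:
    """Adherence mixture emulating a mostly-adherent hypertensive cohort
    (~88% high adherence) with intermediate and low tails."""
    return [
        (0.88, AdherenceProfile(name="high", refill_gap_mean=2, refill_gap_dispersion=0.5)),
        (0.07, AdherenceProfile(name="intermediate", refill_gap_mean=25, refill_gap_dispersion=0.2)),
        (0.05, AdherenceProfile(name="low", refill_gap_mean=60, refill_gap_dispersion=0.0)),
    ]


def default_menu() -> list[RegimenMenuEntry]:
    """Regimen mix: common monotherapies, the studied two- and three-class
    combinations with their characteristic FDC usage, and redundant
    FDC-plus-same-class-single co-prescription at the rates such patterns
    occur in practice."""
    C, A, B, T = DrugClass.CCB, DrugClass.ARB, DrugClass.BETA_BLOCKER, DrugClass.THIAZIDE
    return [
        RegimenMenuEntry(weight=0.24, classes=[C]),
        RegimenMenuEntry(weight=0.18, classes=[A]),
        RegimenMenuEntry(weight=0.05, classes=[B]),
        RegimenMenuEntry(weight=0.02, classes=[DrugClass.ACEI]),
        RegimenMenuEntry(weight=0.005, classes=[DrugClass.ALPHA_BLOCKER]),
        RegimenMenuEntry(weight=0.005, classes=[T]),
        RegimenMenuEntry(weight=0.30, classes=[C, A], p_fdc=0.25, p_redundant_given_fdc=0.149),
        RegimenMenuEntry(weight=0.02, classes=[A, T], p_fdc=0.80, p_redundant_given_fdc=0.037),
        RegimenMenuEntry(weight=0.10, classes=[C, A, B], p_fdc=0.25, p_redundant_given_fdc=0.253),
        RegimenMenuEntry(weight=0.08, classes=[C, A, T], p_fdc=0.50, p_redundant_given_fdc=0.071),
    ]


class GeneratorConfig(BaseModel):
    n_patients: int = Field(ge=0, default=1000)
    strata: list[tuple[float, AdherenceProfile]] = Field(default_factory=default_strata)
    menu: list[RegimenMenuEntry] = Field(default_factory=default_menu)
    comorbidity_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "diabetes": 0.261,
            "dyslipidemia": 0.596,
            "gout_hyperuricemia": 0.189,
            "renal_disease": 0.100,
            "heart_disease": 0.532,
            "cerebrovascular_disease": 0.202,
        }
    )
    hospitalization_prob: float = Field(ge=0, le=1, default=0.17)
    age_mean: float = 70.1
    age_sd: float = 11.5
    age_min: int = 21
    age_max: int = 99
    male_fraction: float = Field(ge=0, le=1, default=0.57)
    days_supplied: int = Field(ge=1, default=30)
    p_twice_daily: float = Field(ge=0, le=1, default=0.25)
    index_period: tuple[dt.date, dt.date] = DEFAULT_INDEX_PERIOD
    followup_days: int = Field(gt=0, default=365)
    lookback_days: int = Field(gt=0, default=365)
    #: Cap refill gaps so every ~3-month persistence sub-window contains a
    #: refill; keeps non-violators compliant with every selection criterion.
    ensure_persistence: bool = True
    persistence_window_days: int = Field(gt=0, default=91)
    violation_rates: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        total = sum(w for w, _ in self.strata)
        if self.strata and abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum weights must sum to 1, got {total}")
        for k, v in self.violation_rates.items():
            if k not in VIOLATION_CRITERIA:
                raise ValueError(f"unknown violation criterion {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"violation rate for {k!r} outside [0, 1]")
        for k, v in self.comorbidity_prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"comorbidity prevalence for {k!r} outside [0, 1]")
        return self

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            index_period=self.index_period,
            lookback_days=self.lookback_days,
            followup_days=self.followup_days,
            persistence_window_days=self.persistence_window_days,
            random_seed=self.seed,
        )


def _draw_gap(profile: AdherenceProfile, rng: np.random.Generator) -> int:
    m = profile.refill_gap_mean
    d = profile.refill_gap_dispersion
    if m == 0:
        return 0
    if d == 0:
        return int(round(m))
    k = 1.0 / d
    return int(rng.negative_binomial(k, k / (k + m)))


def generate_refill_sequence(
    profile: AdherenceProfile,
    product: DrugProduct,
    days_supplied: int,
    window_length: int,
    rng: np.random.Generator,
    *,
    patient_id: str = "P0",
    index_date: dt.date = dt.date(2014, 4, 1),
    pills_per_day: float = 1.0,
    setting: str = "outpatient",
    max_gap: Optional[int] = None,
) -> list[Prescription]:
    """Dispensing sequence for one product over ``[0, window_length)`` days.

    The first dispensing is at day 0; each subsequent one follows after
    ``days_supplied + gap`` days.  The sequence stops at discontinuation
    (Bernoulli per refill) or when the next dispensing would fall outside
    the window.  ``max_gap`` optionally truncates gap draws.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    offsets = [0]
    t = 0
    while True:
        if rng.random() < profile.discontinue_prob_per_refill:
            break
        gap = _draw_gap(profile, rng)
        if max_gap is not None:
            gap = min(gap, max_gap)
        t += days_supplied + gap
        if t >= window_length:
            break
        offsets.append(t)
    return [
        Prescription(
            patient_id=patient_id,
            product_code=product.product_code,
            date=index_date + dt.timedelta(days=off),
            days_supplied=days_supplied,
            pills_per_day=pills_per_day,
            setting=setting,  # type: ignore[arg-type]
        )
        for off in offsets
    ]


def _pick_single(cls: DrugClass, ontology: DrugOntology, rng: np.random.Generator) -> DrugProduct:
    candidates = sorted(
        (p for p in ontology.products.values() if not p.is_fdc and cls in p.classes),
        key=lambda p: p.product_code,
    )
    if not candidates:
        raise ValueError(f"ontology has no single-agent product of class {cls}")
    return candidates[int(rng.integers(len(candidates)))]


def _pick_fdc(
    classes: frozenset[DrugClass], ontology: DrugOntology, rng: np.random.Generator
) -> Optional[DrugProduct]:
    """An FDC whose class set is contained in ``classes``, preferring the
    largest (a triple FDC over a pair when both fit)."""
    candidates = sorted(
        (p for p in ontology.products.values() if p.is_fdc and p.classes <= classes),
        key=lambda p: (-len(p.classes), p.product_code),
    )
    if not candidates:
        return None
    best = len(candidates[0].classes)
    top = [p for p in candidates if len(p.classes) == best]
    return top[int(rng.integers(len(top)))]


def _choose_products(
    entry: RegimenMenuEntry, ontology: DrugOntology, rng: np.random.Generator
) -> tuple[list[DrugProduct], bool, bool]:
    """Resolve a menu entry to concrete products.

    Returns (products, contains_fdc, fdc_redundant)."""
    wanted = frozenset(entry.classes)
    products: list[DrugProduct] = []
    used_fdc = redundant = False
    remaining = set(wanted)
    if len(wanted) >= 2 and rng.random() < entry.p_fdc:
        fdc = _pick_fdc(wanted, ontology, rng)
        if fdc is not None:
            products.append(fdc)
            used_fdc = True
            remaining -= fdc.classes
            if rng.random() < entry.p_redundant_given_fdc:
                shared = sorted(fdc.classes, key=lambda c: c.value)
                cls = shared[int(rng.integers(len(shared)))]
                products.append(_pick_single(cls, ontology, rng))
                redundant = True
    for cls in sorted(remaining, key=lambda c: c.value):
        products.append(_pick_single(cls, ontology, rng))
    return products, used_fdc, redundant


def _birth_year_month(index_date: dt.date, age_years: int, rng: np.random.Generator) -> str:
    """A year-month such that the completed age at ``index_date`` equals
    ``age_years``."""
    month = int(rng.integers(1, 13))
    year = index_date.year - age_years
    if (month, 1) > (index_date.month, index_date.day):
        year -= 1
    return f"{year:04d}-{month:02d}"


def generate_population(
    config: GeneratorConfig,
    ontology: Optional[DrugOntology] = None,
) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a claims dataset plus its ground-truth table.

    The truth table has one row per patient: adherence stratum, expected
    long-run coverage, regimen label, FDC flags and — after
    :func:`inject_violations` — which selection criterion, if any, the
    patient violates.  Fully reproducible from ``config.seed``.
    """
    ontology = ontology or default_ontology()
    rng = np.random.default_rng(config.seed)
    period_start, period_end = config.index_period
    period_span = (period_end - period_start).days + 1

    weights = np.array([w for w, _ in config.strata], dtype=float)
    profiles = [p for _, p in config.strata]
    menu_w = np.array([e.weight for e in config.menu], dtype=float)
    menu_w = menu_w / menu_w.sum()

    max_gap = None
    if config.ensure_persistence:
        max_gap = max(config.persistence_window_days - config.days_supplied, 0)

    patients: list[PatientRecord] = []
    truth_rows: list[dict] = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        stratum_idx = int(rng.choice(len(profiles), p=weights)) if profiles else 0
        profile = profiles[stratum_idx]
        entry = config.menu[int(rng.choice(len(config.menu), p=menu_w))]
        index_date = period_start + dt.timedelta(days=int(rng.integers(period_span)))
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)),
                          config.age_min, config.age_max))
        sex = "male" if rng.random() < config.male_fraction else "female"
        birth_ym = _birth_year_month(index_date, age, rng)

        products, used_fdc, redundant = _choose_products(entry, ontology, rng)
        pills = [2.0 if rng.random() < config.p_twice_daily else 1.0 for _ in products]

        # One refill schedule per patient: all products of the regimen are
        # dispensed at the same visits, as at a single prescribing encounter.
        schedule = generate_refill_sequence(
            profile,
            products[0],
            config.days_supplied,
            config.followup_days,
            rng,
            patient_id=pid,
            index_date=index_date,
            pills_per_day=pills[0],
            max_gap=max_gap,
        )
        offsets = [(rx.date - index_date).days for rx in schedule]
        prescriptions = list(schedule)
        for prod, ppd in zip(products[1:], pills[1:]):
            for off in offsets:
                prescriptions.append(
                    Prescription(
                        patient_id=pid,
                        product_code=prod.product_code,
                        date=index_date + dt.timedelta(days=off),
                        days_supplied=config.days_supplied,
                        pills_per_day=ppd,
                        setting="outpatient",
                    )
                )

        # Look-back treatment history: 1-4 dispensings of the first product,
        # dated before the enrollment period so the index prescription stays
        # the first in-period outpatient dispensing, yet inside the
        # look-back window [index - lookback_days, index).
        n_hist = int(rng.integers(1, 5))
        min_off = (index_date - period_start).days + 1
        hist_offsets = sorted(
            rng.integers(min_off, max(config.lookback_days, min_off) + 1, size=n_hist)
        )
        for off in hist_offsets:
            prescriptions.append(
                Prescription(
                    patient_id=pid,
                    product_code=products[0].product_code,
                    date=index_date - dt.timedelta(days=int(off)),
                    days_supplied=config.days_supplied,
                    pills_per_day=pills[0],
                    setting="outpatient",
                )
            )

        diagnoses = [
            DiagnosisClaim(
                patient_id=pid,
                code=HYPERTENSION_ICD10_PREFIX,
                date=index_date,
                setting="outpatient",
            )
        ]
        comorbidities: dict[str, bool] = {}
        for name, prev in config.comorbidity_prevalence.items():
            has = bool(rng.random() < prev)
            comorbidities[name] = has
            if has:
                dx_off = int(rng.integers(0, config.lookback_days))
                diagnoses.append(
                    DiagnosisClaim(
                        patient_id=pid,
                        code=_COMORBIDITY_DEFAULT_CODE.get(name, "Z00"),
                        date=index_date - dt.timedelta(days=dx_off),
                        setting="outpatient",
                    )
                )
        hospitalized = bool(rng.random() < config.hospitalization_prob)
        if hospitalized:
            # admission diagnosis outside the tracked comorbidity code lists
            dx_off = int(rng.integers(0, config.lookback_days))
            diagnoses.append(
                DiagnosisClaim(
                    patient_id=pid,
                    code="J18",
                    date=index_date - dt.timedelta(days=dx_off),
                    setting="inpatient",
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,  # type: ignore[arg-type]
                birth_year_month=birth_ym,
                diagnoses=diagnoses,
                prescriptions=prescriptions,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "stratum": profile.name,
                "refill_gap_mean": profile.refill_gap_mean,
                "expected_coverage": profile.expected_coverage(config.days_supplied),
                "regimen_label": "+".join(c.value for c in entry.classes),
                "n_products": len(products),
                "contains_fdc": used_fdc,
                "fdc_redundant": redundant,
                "age_at_index": age,
                "sex": sex,
                "index_date": index_date,
                "hospitalized": hospitalized,
                **{f"comorbidity_{k}": v for k, v in comorbidities.items()},
                "violated_criterion": "",
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=list(truth_rows[0].keys()) if truth_rows else ["patient_id", "violated_criterion"],
    )
    dataset = ClaimsDataset(patients=patients)
    if config.violation_rates:
        dataset, truth = inject_violations(
            dataset, truth, config.violation_rates, rng,
            config=config, ontology=ontology,
        )
    return dataset, truth


def _loop_diuretic_code(ontology: DrugOntology) -> str:
    """A single-agent product of an exclusion-relevant class."""
    for p in sorted(ontology.products.values(), key=lambda p: p.product_code):
        if not p.is_fdc and all(c.exclusion_relevant for c in p.classes):
            return p.product_code
    raise ValueError("ontology has no loop-diuretic/aldosterone-antagonist product")


def _mutate_violator(
    patient: PatientRecord,
    criterion: str,
    index_date: dt.date,
    config: GeneratorConfig,
    ontology: DrugOntology,
) -> PatientRecord:
    """Return a minimally-mutated copy of a compliant patient that violates
    exactly ``criterion``."""
    p = patient.model_copy(deep=True)
    if criterion == "age_ge_min":
        p.birth_year_month = f"{index_date.year - 10:04d}-{index_date.month:02d}"
    elif criterion == "hypertension_diagnosis":
        p.diagnoses = [
            d for d in p.diagnoses if not d.code.startswith(HYPERTENSION_ICD10_PREFIX)
        ]
    elif criterion == "index_prescription":
        # no outpatient antihypertensive dispensing may remain anywhere in
        # the enrollment period, or a later one would become the index date
        start, end = config.index_period
        for rx in p.prescriptions:
            if rx.setting == "outpatient" and start <= rx.date <= end:
                rx.setting = "inpatient"
    elif criterion == "lookback_claim":
        p.diagnoses = [d for d in p.diagnoses if d.date >= index_date]
        p.prescriptions = [rx for rx in p.prescriptions if rx.date >= index_date]
    elif criterion == "quarterly_persistence":
        w = config.persistence_window_days
        lo, hi = index_date + dt.timedelta(days=w), index_date + dt.timedelta(days=2 * w)
        p.prescriptions = [rx for rx in p.prescriptions if not (lo <= rx.date < hi)]
    elif criterion == "not_loop_aldosterone_only":
        kept = [rx for rx in p.prescriptions if rx.date != index_date]
        kept.append(
            Prescription(
                patient_id=p.patient_id,
                product_code=_loop_diuretic_code(ontology),
                date=index_date,
                days_supplied=config.days_supplied,
                pills_per_day=1.0,
                setting="outpatient",
            )
        )
        p.prescriptions = kept
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return p


def inject_violations(
    dataset: ClaimsDataset,
    truth: pd.DataFrame,
    violation_rates: dict[str, float],
    rng: np.random.Generator,
    *,
    config: Optional[GeneratorConfig] = None,
    ontology: Optional[DrugOntology] = None,
) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Flip a random subset of compliant patients into single-criterion
    violators at the given per-criterion rates.

    Each flagged patient violates exactly one criterion; the truth table's
    ``violated_criterion`` column records which.
    """
    for k, v in violation_rates.items():
        if k not in VIOLATION_CRITERIA:
            raise ValueError(f"unknown violation criterion {k!r}")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"violation rate for {k!r} outside [0, 1]")

    truth = truth.copy()
    index_dates = dict(zip(truth["patient_id"], truth["index_date"]))
    config = config or GeneratorConfig()
    ontology = ontology or default_ontology()
    new_patients: list[PatientRecord] = []
    for patient in dataset:
        chosen = ""
        for crit in VIOLATION_CRITERIA:
            rate = violation_rates.get(crit, 0.0)
            if rate and rng.random() < rate:
                chosen = crit
                break
        if chosen:
            idx = index_dates[patient.patient_id]
            if isinstance(idx, str):
                idx = dt.date.fromisoformat(idx)
            patient = _mutate_violator(patient, chosen, idx, config, ontology)
            truth.loc[truth["patient_id"] == patient.patient_id, "violated_criterion"] = chosen
        new_patients.append(patient)
    return ClaimsDataset(patients=new_patients), truth
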