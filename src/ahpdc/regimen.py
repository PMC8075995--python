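"""Index-date regimen classification.

Drug counts follow the active-ingredient convention: an FDC of two agents
counts as two drugs, two distinct single agents of the same class count as
two drugs.  Pill counts sum the daily tablets over the antihypertensive
products.  ``fdc_redundant`` flags prescriptions where an FDC is
co-prescribed with a single agent from one of the FDC's own classes —
a pattern that defeats the pill-burden advantage FDCs are meant to provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .model import Prescription, StudyConfig
from .ontology import (
    DrugClass,
    DrugOntology,
    DrugProduct,
    combination_label,
    resolve_classes,
)

CountBasis = Literal["ingredients", "products"]
ExposureCategory = Literal["FDC", "single_drug_combination"]

#: The combination groups compared in the analysis; membership requires the
#: index class set to equal the group's class set exactly, keeping groups
#: disjoint.
COMBINATION_GROUPS: dict[str, frozenset[DrugClass]] = {
    "CCB+ARB": frozenset({DrugClass.CCB, DrugClass.ARB}),
    "ARB+THIAZIDE": frozenset({DrugClass.ARB, DrugClass.THIAZIDE}),
    "CCB+ARB+BETA_BLOCKER": frozenset(
        {DrugClass.CCB, DrugClass.ARB, DrugClass.BETA_BLOCKER}
    ),
    "CCB+ARB+THIAZIDE": frozenset(
        {DrugClass.CCB, DrugClass.ARB, DrugClass.THIAZIDE}
    ),
}


@dataclass(frozen=True)
class IndexRegimen:
    patient_id: str
    products: tuple[DrugProduct, ...]
    pills_per_day: tuple[float, ...]
    n_drugs: int
    n_pills: float
    class_set: frozenset[DrugClass]
    combination_label: str
    contains_fdc: bool
    fdc_redundant: bool


def classify_index_regimen(
    index_prescriptions: Sequence[Prescription],
    ontology: DrugOntology,
    count_basis: CountBasis = "ingredients",
    strict: bool = True,
) -> IndexRegimen:
    """Classify the set of antihypertensive dispensings on the index date.

    Prescriptions whose product is unknown to the ontology are ignored under
    ``strict=False`` (they are treated as non-antihypertensive co-medication)
    and raise otherwise.  Duplicate products are merged with their daily
    pill counts summed.
    """
    if not index_prescriptions:
        raise ValueError("classify_index_regimen requires >=1 index prescription")

    pills: dict[str, float] = {}
    for rx in index_prescriptions:
        if rx.product_code not in ontology:
            # raises under strict mode, warns otherwise
            resolve_classes(rx.product_code, ontology, strict=strict)
            continue
        pills[rx.product_code] = pills.get(rx.product_code, 0.0) + rx.pills_per_day

    if not pills:
        raise ValueError("no antihypertensive products on the index date")

    products = tuple(ontology[code] for code in sorted(pills))
    pid = index_prescriptions[0].patient_id
    class_set = frozenset().union(*(p.classes for p in products))
    if count_basis == "ingredients":
        n_drugs = sum(p.n_agents for p in products)
    else:
        n_drugs = len(products)
    n_pills = sum(pills.values())

    fdcs = [p for p in products if p.is_fdc]
    singles = [p for p in products if not p.is_fdc]
    redundant = any(f.classes & s.classes for f in fdcs for s in singles)

    return IndexRegimen(
        patient_id=pid,
        products=products,
        pills_per_day=tuple(pills[p.product_code] for p in products),
        n_drugs=n_drugs,
        n_pills=n_pills,
        class_set=class_set,
        combination_label=combination_label(class_set),
        contains_fdc=bool(fdcs),
        fdc_redundant=redundant,
    )


def combination_group(regimen: IndexRegimen) -> Optional[str]:
    """The studied combination group whose class set the regimen matches
    exactly, or None."""
    for name, classes in COMBINATION_GROUPS.items():
        if regimen.class_set == classes:
            return name
    return None


def fdc_exposure_category(regimen: IndexRegimen) -> ExposureCategory:
    """FDC if any fixed-dose combination is part of the index prescription
    (redundant co-prescription included); otherwise a combination of single
    drugs."""
    return "FDC" if regimen.contains_fdc else "single_drug_combination"
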