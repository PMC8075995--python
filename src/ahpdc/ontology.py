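"""Product-code to antihypertensive-class mapping, including FDC decomposition.

A fixed-dose combination (FDC) is a single pill containing two or more
active agents, usually from different classes; for all coverage and counting
purposes an FDC is decomposed into its constituent classes.  Loop diuretics
and aldosterone antagonists are antihypertensive products but have major
indications other than hypertension, so a regimen consisting solely of them
is excluded from the cohort; the classes carry an ``exclusion_relevant``
flag for that rule.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

log = logging.getLogger(__name__)


class DrugClass(str, Enum):
    """Closed set of antihypertensive drug classes.

    Enum definition order is the canonical display order used when building
    combination labels such as ``"CCB+ARB+THIAZIDE"``.
    """

    CCB = "CCB"
    ARB = "ARB"
    ACEI = "ACEI"
    BETA_BLOCKER = "BETA_BLOCKER"
    ALPHA_BLOCKER = "ALPHA_BLOCKER"
    THIAZIDE = "THIAZIDE"
    LOOP = "LOOP"
    ALDOSTERONE_ANTAGONIST = "ALDOSTERONE_ANTAGONIST"
    OTHER_AH = "OTHER_AH"

    @property
    def exclusion_relevant(self) -> bool:
        """True for classes with major non-hypertension indications."""
        return self in (DrugClass.LOOP, DrugClass.ALDOSTERONE_ANTAGONIST)


CLASS_ORDER = {c: i for i, c in enumerate(DrugClass)}

EXCLUSION_CLASSES = frozenset({DrugClass.LOOP, DrugClass.ALDOSTERONE_ANTAGONIST})


class OntologyError(ValueError):
    """Raised for malformed ontology files or unknown product codes."""


@dataclass(frozen=True)
class DrugProduct:
    product_code: str
    display_name: str
    classes: frozenset[DrugClass]
    n_agents: int
    atc_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.classes:
            raise OntologyError(f"product {self.product_code!r} has no classes")
        if self.n_agents < 1:
            raise OntologyError(f"product {self.product_code!r}: n_agents must be >= 1")
        if len(self.classes) > self.n_agents:
            raise OntologyError(
                f"product {self.product_code!r}: {len(self.classes)} classes "
                f"exceed {self.n_agents} agents"
            )

    @property
    def is_fdc(self) -> bool:
        return self.n_agents >= 2


@dataclass
class DrugOntology:
    """Map of product codes to :class:`DrugProduct`."""

    products: dict[str, DrugProduct] = field(default_factory=dict)

    def __contains__(self, code: str) -> bool:
        return code in self.products

    def __getitem__(self, code: str) -> DrugProduct:
        try:
            return self.products[code]
        except KeyError:
            raise OntologyError(f"unknown product code {code!r}") from None

    def __len__(self) -> int:
        return len(self.products)

    def add(self, product: DrugProduct) -> None:
        if product.product_code in self.products:
            raise OntologyError(f"duplicate product code {product.product_code!r}")
        self.products[product.product_code] = product


_UNKNOWN_PRODUCT_NAME = "unknown antihypertensive"


def resolve_classes(
    product_code: str, ontology: DrugOntology, strict: bool = True
) -> frozenset[DrugClass]:
    """Return the drug-class set of a product; FDCs yield every constituent class.

    With ``strict=False`` an unknown code maps to ``{OTHER_AH}`` with a
    logged warning instead of raising.
    """
    if product_code in ontology:
        return ontology[product_code].classes
    if strict:
        raise OntologyError(f"unknown product code {product_code!r}")
    log.warning("unknown product code %r mapped to OTHER_AH", product_code)
    return frozenset({DrugClass.OTHER_AH})


def is_excluded_only_regimen(products: Iterable[DrugProduct]) -> bool:
    """True iff every class across the products is a loop diuretic or
    aldosterone antagonist (the "solely" exclusion rule: an FDC spanning a
    kept class keeps the patient in)."""
    products = list(products)
    if not products:
        raise ValueError("is_excluded_only_regimen requires a non-empty product set")
    union: set[DrugClass] = set()
    for p in products:
        union |= p.classes
    return union <= EXCLUSION_CLASSES


def load_ontology(path: Union[str, Path]) -> DrugOntology:
    """Load a TSV ontology: product_code, name, classes (';'-separated),
    n_agents[, atc_code]."""
    path = Path(path)
    ontology = DrugOntology()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["product_code", "name", "classes", "n_agents"]
        missing = [c for c in required if c not in header]
        if missing:
            raise OntologyError(f"ontology {path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            code = cells[idx["product_code"]].strip()
            tokens = [t for t in cells[idx["classes"]].split(";") if t.strip()]
            if not tokens:
                raise OntologyError(f"{path}:{lineno}: product {code!r} has empty classes")
            try:
                classes = frozenset(DrugClass(t.strip()) for t in tokens)
            except ValueError as exc:
                raise OntologyError(f"{path}:{lineno}: {exc}") from None
            atc = None
            if "atc_code" in idx and len(cells) > idx["atc_code"]:
                atc = cells[idx["atc_code"]].strip() or None
            ontology.add(
                DrugProduct(
                    product_code=code,
                    display_name=cells[idx["name"]].strip(),
                    classes=classes,
                    n_agents=int(cells[idx["n_agents"]]),
                    atc_code=atc,
                )
            )
    return ontology


def default_ontology() -> DrugOntology:
    """The formulary shipped with the package.

    Synthetic fixture of ~25 representative Japanese antihypertensive
    products (single agents of every class plus the marketed FDC patterns:
    CCB+ARB, ARB+thiazide and CCB+ARB+thiazide); it is an emulation for
    testing and simulation, not an authoritative coding dictionary.
    """
    resource = importlib.resources.files("ahpdc.data").joinpath("default_ontology.tsv")
    with importlib.resources.as_file(resource) as path:
        return load_ontology(path)


def combination_label(classes: Iterable[DrugClass]) -> str:
    """Canonical '+'-joined label with classes in fixed display order."""
    return "+".join(c.value for c in sorted(set(classes), key=CLASS_ORDER.__getitem__))
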