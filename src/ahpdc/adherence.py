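"""Proportion-of-days-covered (PDC) computation over the follow-up window.

PDC = (number of follow-up days on which the drugs of interest were
supplied) / (number of days in the follow-up window), with each calendar
day counted at most once.  Two overlap policies are supported:

``UNION``
    A day is covered if at least one supply spans it; overlapping supplies
    are merged (the standard PDC convention).

``SHIFT_FORWARD``
    Dispensings are processed in date order and a supply that overlaps the
    previously covered span is assumed to be stockpiled: it starts the day
    after that span ends.  This credits early refills with future coverage
    and therefore never yields fewer covered days than ``UNION``.

Intervals are integer day offsets from the index date, half-open
``[start, end)``, clipped to ``[0, followup_days)``.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .model import Prescription, StudyConfig
from .ontology import DrugClass, DrugOntology, resolve_classes

log = logging.getLogger(__name__)

Policy = Literal["UNION", "SHIFT_FORWARD"]
Mode = Literal["ANY", "ALL"]
Category = Literal["high", "intermediate", "low"]

Interval = tuple[int, int]


@dataclass(frozen=True)
class AdherenceRecord:
    patient_id: str
    pdc: float
    category: Category
    covered_days: int
    window_days: int
    drugs_of_interest: frozenset[DrugClass]
    mode: Mode
    policy: Policy


def categorize_pdc(pdc: float, bounds: tuple[float, float] = (0.80, 0.40)) -> Category:
    """Assign the adherence category for a PDC fraction.

    ``bounds`` is ``(high, low)``: high iff pdc >= high, low iff pdc < low,
    intermediate otherwise.  The conventional integer-percent labels
    ("40-79%", "<=39%") are read as half-open fraction intervals so that
    every value in [0, 1] is classifiable.
    """
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"pdc must be in [0, 1], got {pdc}")
    high, low = bounds
    if pdc >= high:
        return "high"
    if pdc < low:
        return "low"
    return "intermediate"


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge possibly-overlapping intervals into a sorted disjoint list."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def coverage_intervals(
    prescriptions: Sequence[Prescription],
    index_date: dt.date,
    followup_days: int,
    policy: Policy = "UNION",
) -> list[Interval]:
    """Covered day intervals from a set of dispensings, clipped to the window.

    A prescription dated before the index date is flagged with a warning but
    the part of its supply that reaches into the window still counts.
    """
    if followup_days <= 0:
        raise ValueError("followup_days must be positive")
    raw: list[Interval] = []
    n_pre_index = 0
    for rx in sorted(prescriptions, key=lambda r: (r.date, -r.days_supplied)):
        offset = (rx.date - index_date).days
        if offset < 0:
            n_pre_index += 1
        raw.append((offset, offset + rx.days_supplied))
    if n_pre_index:
        log.warning(
            "%d prescription(s) dated before index %s; only their in-window "
            "supply counts",
            n_pre_index, index_date,
        )

    if policy == "UNION":
        covered = raw
    elif policy == "SHIFT_FORWARD":
        covered = []
        frontier: Optional[int] = None
        for start, end in raw:  # already date-ordered
            if frontier is not None and start < frontier:
                start, end = frontier, frontier + (end - start)
            covered.append((start, end))
            frontier = max(frontier, end) if frontier is not None else end
    else:
        raise ValueError(f"unknown overlap policy {policy!r}")

    clipped = [(max(s, 0), min(e, followup_days)) for s, e in covered]
    return _merge(clipped)


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted disjoint interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_days(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def compute_pdc(
    prescriptions: Sequence[Prescription],
    index_date: dt.date,
    config: StudyConfig,
    ontology: DrugOntology,
    drugs_of_interest: Iterable[DrugClass],
    mode: Mode = "ANY",
    *,
    patient_id: Optional[str] = None,
    strict: bool = True,
) -> AdherenceRecord:
    """PDC for a class set of interest under the configured policy.

    ``ANY``: a day counts if any product whose class set intersects the
    classes of interest supplies it.  ``ALL``: a day counts only if every
    class of interest is supplied on that day (an FDC supplies all its
    constituent classes simultaneously); this is the natural adherence
    measure for a specific combination regimen.
    """
    interest = frozenset(drugs_of_interest)
    if not interest:
        raise ValueError("drugs_of_interest must be non-empty")

    def qualifying(rx: Prescription) -> bool:
        if not config.inpatient_supply_counts and rx.setting == "inpatient":
            return False
        return bool(resolve_classes(rx.product_code, ontology, strict=strict) & interest)

    relevant = [rx for rx in prescriptions if qualifying(rx)]
    window = config.followup_days

    if mode == "ANY":
        intervals = coverage_intervals(relevant, index_date, window, config.overlap_policy)
    elif mode == "ALL":
        intervals = [(0, window)]
        for cls in interest:
            stream = [
                rx for rx in relevant
                if cls in resolve_classes(rx.product_code, ontology, strict=strict)
            ]
            per_class = coverage_intervals(stream, index_date, window, config.overlap_policy)
            intervals = intersect_intervals(intervals, per_class)
    else:
        raise ValueError(f"unknown PDC mode {mode!r}")

    covered = total_days(intervals)
    pdc = covered / window
    pid = patient_id or (prescriptions[0].patient_id if prescriptions else "")
    return AdherenceRecord(
        patient_id=pid,
        pdc=pdc,
        category=categorize_pdc(pdc, config.pdc_category_bounds),
        covered_days=covered,
        window_days=window,
        drugs_of_interest=interest,
        mode=mode,
        policy=config.overlap_policy,
    )
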