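"""Summary tables and statistical comparisons.

Produces the study's deliverables from the per-patient analysis frame:
a demographics/characteristics table stratified by adherence category,
mean PDC by index drug/pill count, combination-regimen adherence with
FDC-versus-single-drug comparisons, and FDC redundancy frequencies.
Group means are compared with Welch's unequal-variance t-test (a pooled
Student's t is available as a sensitivity switch); no multiple-testing
correction is applied.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adherence import AdherenceRecord, compute_pdc
from .cohort import CohortResult
from .model import ClaimsDataset, StudyConfig
from .ontology import DrugClass, DrugOntology
from .regimen import (
    COMBINATION_GROUPS,
    IndexRegimen,
    classify_index_regimen,
    combination_group,
    fdc_exposure_category,
)

ADHERENCE_STRATA = ["overall", "high", "intermediate", "low"]


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up to one
    decimal, the display convention for count-based table cells."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    count: Optional[int] = None
    percent: Optional[float] = None


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided t-test of two groups of PDC values (Welch by default).

    Degenerate zero-variance groups are handled explicitly: equal means
    give t = 0, p = 1; unequal means with no variance give an infinite
    statistic (sign follows mean_a - mean_b) and p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a, var_b = float(a.var(ddof=1)), float(b.var(ddof=1))
    n_a, n_b = len(a), len(b)

    # detect degenerate groups by range, not variance: float cancellation can
    # leave a tiny nonzero variance for identical values
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        df = float(n_a + n_b - 2)
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean_a - mean_b), 0.0
    elif equal_var:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(n_a + n_b - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        sa, sb = var_a / n_a, var_b / n_b
        df = (sa + sb) ** 2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))

    return ComparisonResult(
        group_a=label_a, group_b=label_b,
        n_a=n_a, n_b=n_b,
        mean_a=mean_a, mean_b=mean_b,
        t_statistic=t_stat, degrees_of_freedom=df, p_value=p,
    )


def assemble_analysis_frame(
    dataset: ClaimsDataset,
    cohort: CohortResult,
    config: StudyConfig,
    ontology: DrugOntology,
    strict: bool = True,
) -> pd.DataFrame:
    """One row per included patient with everything the report tables need:
    demographics, comorbidity flags (ICD-10 prefix match on claims in the
    look-back window through the index date), hospitalization flag (any
    inpatient claim during observation), index-regimen counts and flags,
    and overall PDC (all antihypertensive classes, ANY mode) with its
    category."""
    all_classes = frozenset(DrugClass)
    rows = []
    for pid, index_date in cohort.included:
        patient = dataset.get(pid)
        if patient is None:
            raise KeyError(f"cohort patient {pid!r} not in dataset")
        adherence = compute_pdc(
            patient.prescriptions, index_date, config, ontology,
            all_classes, mode="ANY", patient_id=pid, strict=strict,
        )
        index_rx = [
            rx for rx in patient.prescriptions
            if rx.date == index_date and rx.setting == "outpatient"
            and rx.product_code in ontology
        ]
        regimen = classify_index_regimen(
            index_rx, ontology, config.drug_count_basis, strict=strict
        )
        group = combination_group(regimen)

        lb_start = index_date - dt.timedelta(days=config.lookback_days)
        baseline_codes = {
            d.code for d in patient.diagnoses if lb_start <= d.date <= index_date
        }
        comorbid = {
            f"comorbidity_{name}": any(
                code.startswith(tuple(prefixes)) for code in baseline_codes
            )
            for name, prefixes in config.comorbidity_codes.items()
        }
        fu_end = index_date + dt.timedelta(days=config.followup_days)
        hospitalized = any(
            rec.setting == "inpatient" and lb_start <= rec.date < fu_end
            for rec in (*patient.diagnoses, *patient.prescriptions)
        )
        rows.append(
            {
                "patient_id": pid,
                "index_date": index_date,
                "age": patient.age_at(index_date),
                "sex": patient.sex,
                "pdc": adherence.pdc,
                "category": adherence.category,
                "covered_days": adherence.covered_days,
                "window_days": adherence.window_days,
                "n_drugs": regimen.n_drugs,
                "n_pills": regimen.n_pills,
                "combination_label": regimen.combination_label,
                "group": group or "",
                "contains_fdc": regimen.contains_fdc,
                "fdc_redundant": regimen.fdc_redundant,
                "exposure_category": fdc_exposure_category(regimen),
                "hospitalized": hospitalized,
                **comorbid,
            }
        )
    return pd.DataFrame(rows)


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "overall":
        return pd.Series(True, index=df.index)
    return df["category"] == stratum


def summarize_by_category(analysis: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Tidy demographics/characteristics table: one row per (variable,
    stratum) with n and either mean/sd or count/percent.  Empty strata keep
    their n = 0 row with blank statistics."""
    continuous = [("age", "age"), ("n_drugs", "n_drugs"), ("n_pills", "n_pills")]
    flags = [("male", analysis["sex"] == "male" if len(analysis) else pd.Series(dtype=bool))]
    for name in config.comorbidity_codes:
        col = f"comorbidity_{name}"
        flags.append((name, analysis[col] if col in analysis else pd.Series(dtype=bool)))
    flags.append(("hospitalized", analysis["hospitalized"] if len(analysis) else pd.Series(dtype=bool)))

    rows = []
    for stratum in ADHERENCE_STRATA:
        mask = _stratum_mask(analysis, stratum) if len(analysis) else pd.Series(dtype=bool)
        sub = analysis[mask] if len(analysis) else analysis
        n = len(sub)
        rows.append({"variable": "n", "stratum": stratum, "n": n,
                     "mean": None, "sd": None, "count": None, "percent": None})
        for label, col in continuous:
            vals = sub[col] if n else pd.Series(dtype=float)
            rows.append({
                "variable": label, "stratum": stratum, "n": n,
                "mean": float(vals.mean()) if n else None,
                "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else None),
                "count": None, "percent": None,
            })
        for label, series in flags:
            count = int(series[mask].sum()) if n else 0
            rows.append({
                "variable": label, "stratum": stratum, "n": n,
                "mean": None, "sd": None,
                "count": count,
                "percent": proportion(count, n) if n else None,
            })
    return pd.DataFrame(rows)


def mean_pdc_by_count(
    analysis: pd.DataFrame,
    count_type: Literal["drugs", "pills"] = "drugs",
    top_bin: int = 5,
) -> pd.DataFrame:
    """Mean PDC by number of index drugs or pills, pooling counts >=
    ``top_bin``; each bin is also compared against the 1-count bin."""
    col = "n_drugs" if count_type == "drugs" else "n_pills"
    counts = analysis[col].astype(float)
    binned = counts.clip(upper=top_bin).astype(int)
    labels = {i: str(i) for i in range(1, top_bin)} | {top_bin: f">={top_bin}"}

    ref = analysis.loc[binned == 1, "pdc"]
    rows = []
    for b in range(1, top_bin + 1):
        vals = analysis.loc[binned == b, "pdc"]
        n = len(vals)
        row = {
            "bin": labels[b], "n": n,
            "mean_pdc": float(vals.mean()) if n else None,
            "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else None),
            "se": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None,
            "p_vs_1": None,
        }
        if b > 1 and n >= 2 and len(ref) >= 2:
            row["p_vs_1"] = compare_groups(ref, vals, "1", labels[b]).p_value
        rows.append(row)
    return pd.DataFrame(rows)


def regimen_adherence_table(
    analysis: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-combination-group adherence split by FDC exposure, plus the
    planned comparisons (between the paired groups, and FDC vs single-drug
    within each group).  Under-sized comparisons are recorded as skipped
    with a reason rather than dropped."""
    rows = []
    for group in COMBINATION_GROUPS:
        for exposure in ("FDC", "single_drug_combination"):
            vals = analysis.loc[
                (analysis["group"] == group)
                & (analysis["exposure_category"] == exposure),
                "pdc",
            ]
            n = len(vals)
            rows.append({
                "group": group, "exposure": exposure, "n": n,
                "mean_pdc": float(vals.mean()) if n else None,
                "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else None),
            })
    table = pd.DataFrame(rows)

    comparisons = []

    def _compare(label: str, a: pd.Series, b: pd.Series, name_a: str, name_b: str):
        if len(a) < 2 or len(b) < 2:
            comparisons.append({
                "comparison": label, "n_a": len(a), "n_b": len(b),
                "mean_a": float(a.mean()) if len(a) else None,
                "mean_b": float(b.mean()) if len(b) else None,
                "t": None, "df": None, "p_value": None,
                "skipped_reason": "fewer than 2 observations in a group",
            })
            return
        res = compare_groups(a, b, name_a, name_b, equal_var=config.equal_variance_ttest)
        comparisons.append({
            "comparison": label, "n_a": res.n_a, "n_b": res.n_b,
            "mean_a": res.mean_a, "mean_b": res.mean_b,
            "t": res.t_statistic, "df": res.degrees_of_freedom,
            "p_value": res.p_value, "skipped_reason": "",
        })

    def _group_vals(group: str) -> pd.Series:
        return analysis.loc[analysis["group"] == group, "pdc"]

    _compare("CCB+ARB vs ARB+THIAZIDE",
             _group_vals("CCB+ARB"), _group_vals("ARB+THIAZIDE"),
             "CCB+ARB", "ARB+THIAZIDE")
    _compare("CCB+ARB+BETA_BLOCKER vs CCB+ARB+THIAZIDE",
             _group_vals("CCB+ARB+BETA_BLOCKER"), _group_vals("CCB+ARB+THIAZIDE"),
             "CCB+ARB+BETA_BLOCKER", "CCB+ARB+THIAZIDE")
    for group in COMBINATION_GROUPS:
        sub = analysis[analysis["group"] == group]
        _compare(
            f"{group}: FDC vs single_drug_combination",
            sub.loc[sub["exposure_category"] == "FDC", "pdc"],
            sub.loc[sub["exposure_category"] == "single_drug_combination", "pdc"],
            "FDC", "single_drug_combination",
        )
    return table, pd.DataFrame(comparisons)


def fdc_pattern_frequencies(analysis: pd.DataFrame) -> pd.DataFrame:
    """Per combination group: percentage of FDC-containing index
    prescriptions that also include a single agent from one of the FDC's
    own classes."""
    rows = []
    for group in COMBINATION_GROUPS:
        sub = analysis[(analysis["group"] == group) & analysis["contains_fdc"]]
        n_fdc = len(sub)
        n_red = int(sub["fdc_redundant"].sum()) if n_fdc else 0
        rows.append({
            "group": group,
            "n_fdc": n_fdc,
            "n_redundant": n_red,
            "percent_redundant": proportion(n_red, n_fdc) if n_fdc else None,
            "skipped_reason": "" if n_fdc else "no FDC-containing regimens",
        })
    return pd.DataFrame(rows)


def format_markdown(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"
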