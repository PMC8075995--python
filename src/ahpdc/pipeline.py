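"""End-to-end study driver: dataset -> cohort -> adherence -> tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import CohortResult, apply_selection
from .model import ClaimsDataset, StudyConfig
from .ontology import DrugOntology, default_ontology
from .report import (
    assemble_analysis_frame,
    fdc_pattern_frequencies,
    format_markdown,
    mean_pdc_by_count,
    regimen_adherence_table,
    summarize_by_category,
)


@dataclass
class StudyResults:
    cohort: CohortResult
    analysis: pd.DataFrame
    table1: pd.DataFrame
    pdc_by_drugs: pd.DataFrame
    pdc_by_pills: pd.DataFrame
    regimen_table: pd.DataFrame
    comparisons: pd.DataFrame
    fdc_patterns: pd.DataFrame

    def write(self, out_dir: Path, fmt: str = "csv") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {
            "attrition": self.cohort.attrition_frame(),
            "cohort": self.cohort.cohort_frame(),
            "adherence": self.analysis[
                ["patient_id", "pdc", "category", "covered_days", "window_days"]
            ],
            "regimens": self.analysis[
                ["patient_id", "n_drugs", "n_pills", "combination_label", "group",
                 "contains_fdc", "fdc_redundant", "exposure_category"]
            ],
            "table1": self.table1,
            "fig2_drugs": self.pdc_by_drugs,
            "fig2_pills": self.pdc_by_pills,
            "regimen_adherence": self.regimen_table,
            "comparisons": self.comparisons,
            "fdc_patterns": self.fdc_patterns,
        }
        for name, df in tables.items():
            if fmt == "md":
                (out_dir / f"{name}.md").write_text(format_markdown(df))
            else:
                df.to_csv(out_dir / f"{name}.csv", index=False, lineterminator="\n")


def run_study(
    dataset: ClaimsDataset,
    config: Optional[StudyConfig] = None,
    ontology: Optional[DrugOntology] = None,
    strict: bool = True,
) -> StudyResults:
    """Select the cohort, compute adherence and regimens, build all tables."""
    config = config or StudyConfig()
    ontology = ontology or default_ontology()
    cohort = apply_selection(dataset, config, ontology, strict=strict)
    analysis = assemble_analysis_frame(dataset, cohort, config, ontology, strict=strict)
    regimen_table, comparisons = regimen_adherence_table(analysis, config)
    return StudyResults(
        cohort=cohort,
        analysis=analysis,
        table1=summarize_by_category(analysis, config),
        pdc_by_drugs=mean_pdc_by_count(analysis, "drugs"),
        pdc_by_pills=mean_pdc_by_count(analysis, "pills"),
        regimen_table=regimen_table,
        comparisons=comparisons,
        fdc_patterns=fdc_pattern_frequencies(analysis),
    )
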