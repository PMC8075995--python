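"""Readers and writers for the on-disk claims layout, plus config loading.

CSV dialect: a directory holding three files joined on ``patient_id`` —

* ``patients.csv``: patient_id, sex, birth_year_month (``YYYY-MM``)
* ``diagnoses.csv``: patient_id, icd10, date, setting
* ``prescriptions.csv``: patient_id, product_code, date, days_supplied,
  pills_per_day, setting

JSONL dialect: a single file with one JSON-encoded patient record per line.
Dates are ISO-8601.  Writers emit rows sorted by (patient_id, date) so a
dataset written twice produces byte-identical files.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .model import ClaimsDataset, DiagnosisClaim, PatientRecord, Prescription, StudyConfig

log = logging.getLogger(__name__)

Dialect = Literal["csv", "jsonl"]

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year_month"]
DIAGNOSIS_COLUMNS = ["patient_id", "icd10", "date", "setting"]
PRESCRIPTION_COLUMNS = [
    "patient_id", "product_code", "date", "days_supplied", "pills_per_day", "setting",
]


class SchemaError(ValueError):
    """A file does not match the documented column layout."""


@dataclass
class RowError:
    file: str
    line: int
    message: str


@dataclass
class ReadReport:
    rows_read: dict[str, int] = field(default_factory=dict)
    errors: list[RowError] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def read_claims(
    path: Union[str, Path],
    dialect: Dialect = "csv",
    on_error: Literal["raise", "skip"] = "raise",
) -> tuple[ClaimsDataset, ReadReport]:
    """Read a claims dataset.

    Malformed rows are collected with file name and line number; with
    ``on_error="skip"`` they are dropped (and reported), otherwise the first
    batch of errors raises.  Row counts per file are logged and returned so
    no well-formed row can be dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        dataset, report = _read_csv_dir(path)
    elif dialect == "jsonl":
        dataset, report = _read_jsonl(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if report.errors and on_error == "raise":
        detail = "; ".join(f"{e.file}:{e.line}: {e.message}" for e in report.errors[:10])
        raise ValueError(f"{len(report.errors)} malformed row(s): {detail}")
    for fname, n in report.rows_read.items():
        log.info("read %d row(s) from %s", n, fname)
    return dataset, report


def _read_csv_dir(path: Path) -> tuple[ClaimsDataset, ReadReport]:
    report = ReadReport()
    patients_df = pd.read_csv(path / "patients.csv", dtype=str, keep_default_na=False)
    dx_df = pd.read_csv(path / "diagnoses.csv", dtype=str, keep_default_na=False)
    rx_df = pd.read_csv(path / "prescriptions.csv", dtype=str, keep_default_na=False)
    _require_columns(patients_df, PATIENT_COLUMNS, path / "patients.csv")
    _require_columns(dx_df, DIAGNOSIS_COLUMNS, path / "diagnoses.csv")
    _require_columns(rx_df, PRESCRIPTION_COLUMNS, path / "prescriptions.csv")
    report.rows_read = {
        "patients.csv": len(patients_df),
        "diagnoses.csv": len(dx_df),
        "prescriptions.csv": len(rx_df),
    }

    diagnoses: dict[str, list[DiagnosisClaim]] = {}
    for i, row in enumerate(dx_df.itertuples(index=False), start=2):
        try:
            dx = DiagnosisClaim(
                patient_id=row.patient_id,
                code=row.icd10,
                date=_parse_date(row.date),
                setting=row.setting,
            )
            diagnoses.setdefault(dx.patient_id, []).append(dx)
        except (ValueError, ValidationError) as exc:
            report.errors.append(RowError("diagnoses.csv", i, str(exc)))

    prescriptions: dict[str, list[Prescription]] = {}
    for i, row in enumerate(rx_df.itertuples(index=False), start=2):
        try:
            rx = Prescription(
                patient_id=row.patient_id,
                product_code=row.product_code,
                date=_parse_date(row.date),
                days_supplied=int(row.days_supplied),
                pills_per_day=float(row.pills_per_day),
                setting=row.setting,
            )
            prescriptions.setdefault(rx.patient_id, []).append(rx)
        except (ValueError, ValidationError) as exc:
            report.errors.append(RowError("prescriptions.csv", i, str(exc)))

    patients: list[PatientRecord] = []
    for i, row in enumerate(patients_df.itertuples(index=False), start=2):
        try:
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    sex=row.sex,
                    birth_year_month=row.birth_year_month,
                    diagnoses=diagnoses.get(row.patient_id, []),
                    prescriptions=prescriptions.get(row.patient_id, []),
                )
            )
        except (ValueError, ValidationError) as exc:
            report.errors.append(RowError("patients.csv", i, str(exc)))
    return ClaimsDataset(patients=patients), report


def _read_jsonl(path: Path) -> tuple[ClaimsDataset, ReadReport]:
    report = ReadReport()
    patients: list[PatientRecord] = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                patients.append(PatientRecord.model_validate_json(line))
            except (ValueError, ValidationError) as exc:
                report.errors.append(RowError(Path(path).name, i, str(exc)))
    report.rows_read = {Path(path).name: len(patients) + len(report.errors)}
    return ClaimsDataset(patients=patients), report


def dataset_frames(dataset: ClaimsDataset) -> dict[str, pd.DataFrame]:
    """The three claims tables as DataFrames, deterministically ordered."""
    pat_rows, dx_rows, rx_rows = [], [], []
    for p in sorted(dataset.patients, key=lambda p: p.patient_id):
        pat_rows.append((p.patient_id, p.sex, p.birth_year_month))
        for d in sorted(p.diagnoses, key=lambda d: (d.date, d.code, d.setting)):
            dx_rows.append((d.patient_id, d.code, d.date.isoformat(), d.setting))
        for r in sorted(p.prescriptions, key=lambda r: (r.date, r.product_code, r.setting)):
            rx_rows.append(
                (r.patient_id, r.product_code, r.date.isoformat(),
                 r.days_supplied, r.pills_per_day, r.setting)
            )
    return {
        "patients": pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS),
        "diagnoses": pd.DataFrame(dx_rows, columns=DIAGNOSIS_COLUMNS),
        "prescriptions": pd.DataFrame(rx_rows, columns=PRESCRIPTION_COLUMNS),
    }


def write_claims(
    dataset: ClaimsDataset, path: Union[str, Path], dialect: Dialect = "csv"
) -> Path:
    """Write a dataset; output is deterministic and re-readable by
    :func:`read_claims`."""
    path = Path(path)
    if dialect == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in dataset_frames(dataset).items():
            df.to_csv(path / f"{name}.csv", index=False, lineterminator="\n")
    elif dialect == "jsonl":
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            for p in sorted(dataset.patients, key=lambda p: p.patient_id):
                ordered = p.model_copy(
                    update={
                        "diagnoses": sorted(
                            p.diagnoses, key=lambda d: (d.date, d.code, d.setting)
                        ),
                        "prescriptions": sorted(
                            p.prescriptions, key=lambda r: (r.date, r.product_code, r.setting)
                        ),
                    }
                )
                fh.write(json.dumps(json.loads(ordered.model_dump_json()), sort_keys=True))
                fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load a study configuration from YAML or JSON; an empty file yields
    all defaults.  Validation errors name the offending field."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping, got {type(data).__name__}")
    try:
        return StudyConfig(**data)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(x) for x in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ValueError(f"invalid config {path}: field(s) {fields}: {exc}") from exc
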