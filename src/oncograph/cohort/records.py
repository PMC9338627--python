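"""Cohort record types and delimited-table persistence.

A cohort is persisted as six TSV tables under one directory:
``patients.tsv``, ``reports.tsv``, ``findings.tsv``, ``diagnoses.tsv``,
``medications.tsv`` and ``notes.tsv``.  All dates are ISO-8601; empty string
means absent.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

from ..errors import CohortParseError


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    clinic_number: str
    first_name: str
    last_name: str
    dob: dt.date
    sex: str
    race: str
    ethnicity: str
    death_date: Optional[dt.date]
    last_contact_date: Optional[dt.date]


@dataclass(frozen=True)
class GeneticReport:
    report_id: str
    patient_id: str
    clinic_number: str
    first_name: str
    last_name: str
    dob: Optional[dt.date]
    panel: str
    receipt_date: dt.date


@dataclass(frozen=True)
class ReportFinding:
    report_id: str
    patient_id: str
    gene: str
    variant: str


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    disease: str
    date: Optional[dt.date]
    stage: str
    source: str  # report | warehouse


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    drug: str
    date: Optional[dt.date]
    source: str  # warehouse | notes


@dataclass(frozen=True)
class NoteSentence:
    patient_id: str
    date: dt.date
    text: str


@dataclass
class SyntheticCohort:
    patients: list
    reports: list
    findings: list
    diagnoses: list
    medications: list
    note_sentences: list

    def __eq__(self, other):
        if not isinstance(other, SyntheticCohort):
            return NotImplemented
        return (self.patients == other.patients
                and self.reports == other.reports
                and self.findings == other.findings
                and self.diagnoses == other.diagnoses
                and self.medications == other.medications
                and self.note_sentences == other.note_sentences)

    def check_invariants(self) -> None:
        ids = {p.patient_id for p in self.patients}
        for name, rows in (("reports", self.reports),
                           ("findings", self.findings),
                           ("diagnoses", self.diagnoses),
                           ("medications", self.medications),
                           ("note_sentences", self.note_sentences)):
            for r in rows:
                if r.patient_id not in ids:
                    raise ValueError(
                        f"{name} row references unknown patient "
                        f"{r.patient_id!r}")


_TABLES = {
    "patients.tsv": PatientRecord,
    "reports.tsv": GeneticReport,
    "findings.tsv": ReportFinding,
    "diagnoses.tsv": DiagnosisRecord,
    "medications.tsv": MedicationRecord,
    "notes.tsv": NoteSentence,
}

_ATTRS = {
    "patients.tsv": "patients",
    "reports.tsv": "reports",
    "findings.tsv": "findings",
    "diagnoses.tsv": "diagnoses",
    "medications.tsv": "medications",
    "notes.tsv": "note_sentences",
}

_DATE_FIELDS = {"dob", "death_date", "last_contact_date", "receipt_date",
                "date"}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for fname, cls in _TABLES.items():
        cols = [f.name for f in fields(cls)]
        path = directory / fname
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(cols)
            for rec in getattr(cohort, _ATTRS[fname]):
                w.writerow([_cell(getattr(rec, c)) for c in cols])
        written.append(path)
    return written


def _parse_value(fname, cls, fieldname, raw, lineno):
    if fieldname in _DATE_FIELDS:
        if raw == "":
            return None
        try:
            return dt.date.fromisoformat(raw)
        except ValueError:
            raise CohortParseError(
                fname, lineno, f"bad date {raw!r} in column {fieldname!r}")
    return raw


def read_cohort(directory) -> SyntheticCohort:
    directory = Path(directory)
    data = {}
    for fname, cls in _TABLES.items():
        path = directory / fname
        cols = [f.name for f in fields(cls)]
        if not path.exists():
            raise CohortParseError(path, 0, "missing table")
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise CohortParseError(path, 1, "empty file, header expected")
            if header != cols:
                missing = set(cols) - set(header)
                raise CohortParseError(
                    path, 1,
                    f"bad header: missing columns {sorted(missing)}"
                    if missing else f"bad header order {header}")
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(cols):
                    raise CohortParseError(
                        path, lineno,
                        f"expected {len(cols)} fields, got {len(row)}")
                kwargs = {
                    c: _parse_value(path, cls, c, v, lineno)
                    for c, v in zip(cols, row)
                }
                rows.append(cls(**kwargs))
        data[_ATTRS[fname]] = rows
    cohort = SyntheticCohort(**data)
    cohort.check_invariants()
    return cohort
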