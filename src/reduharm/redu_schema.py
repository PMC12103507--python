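"""The harmonized metadata table: schema registry, acceptance, validation, I/O.

The output of the whole pipeline is a single TSV table, one row per raw
file, keyed by MRI, with every populated cell drawn from a controlled
vocabulary. The column registry ships as a packaged TSV
(``data/schema.tsv``) and is the single source of truth for column order
and validation kind; allowed terms come from ``data/allowed_terms.tsv``
plus the ontology registries feeding each column.

The acceptance rule: a raw file enters the table only when at least one
piece of *sample-descriptive* metadata is available — analyzed organism,
body part, or sample type (a solvent blank counts). Technical metadata
alone (instrument, chromatography, ...) never qualifies a record.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from . import vocabulary
from .identifiers import MsRunIdentifier, format_mri, parse_mri

#: Canonical filler for absent values — explicit, never an empty cell.
MISSING = "missing value"

#: Fields whose presence makes a record sample-descriptive (acceptance rule).
DESCRIPTIVE_FIELDS = ("NCBITaxonomy", "UBERONBodyPartName", "SampleType")

_TAXONOMY_FORM = re.compile(r"\d+\|.+")
_COORDINATE_FORM = re.compile(r"(-?\d+(?:\.\d+)?)\|(-?\d+(?:\.\d+)?)")


@dataclass(frozen=True)
class SchemaColumn:
    name: str
    kind: str  # key | repository | taxonomy | vocab | year | coordinate | free
    description: str = ""


class Schema:
    """Column registry + allowed-term registries for validation."""

    def __init__(
        self,
        columns: list[SchemaColumn],
        allowed_terms: dict[str, set[str]],
        registries: dict[str, vocabulary.OntologyRegistry] | None = None,
    ) -> None:
        self.columns = columns
        self.by_name = {c.name: c for c in columns}
        self._allowed = {col: set(terms) for col, terms in allowed_terms.items()}
        for column, domains in vocabulary.COLUMN_DOMAINS.items():
            if column in self.by_name and self.by_name[column].kind == "vocab":
                pool = self._allowed.setdefault(column, set())
                for domain in domains:
                    if registries and domain in registries:
                        pool.update(registries[domain].terms())

    @property
    def column_order(self) -> list[str]:
        return [c.name for c in self.columns]

    def allowed_terms(self, column: str) -> set[str]:
        return self._allowed.get(column, set())

    def check_value(self, column: str, value: str) -> str | None:
        """None if valid, else a human-readable failure message."""
        col = self.by_name.get(column)
        if col is None:
            return f"unknown column {column!r}"
        if value == MISSING:
            return None
        if col.kind == "vocab":
            if value not in self._allowed.get(column, set()):
                return f"term {value!r} not in the allowed vocabulary for {column}"
        elif col.kind == "taxonomy":
            if not _TAXONOMY_FORM.fullmatch(value):
                return f"taxonomy term {value!r} is not in 'taxid|name' form"
        elif col.kind == "year":
            if not (value.isdigit() and 1900 <= int(value) <= 2100):
                return f"{value!r} is not a plausible four-digit year"
        elif col.kind == "coordinate":
            m = _COORDINATE_FORM.fullmatch(value)
            if not m or not (-90 <= float(m.group(1)) <= 90 and -180 <= float(m.group(2)) <= 180):
                return f"{value!r} is not a 'lat|lon' coordinate pair"
        elif col.kind == "repository":
            if value not in {"GNPS/MassIVE", "MTBLS", "NMDR"}:
                return f"unknown repository {value!r}"
        return None

    @classmethod
    def default(cls) -> "Schema":
        base = resources.files("reduharm.data")
        columns = []
        with (base / "schema.tsv").open(encoding="utf-8") as handle:
            for rec in csv.DictReader(handle, delimiter="\t"):
                columns.append(SchemaColumn(rec["column"], rec["kind"], rec.get("description", "")))
        allowed: dict[str, set[str]] = {}
        with (base / "allowed_terms.tsv").open(encoding="utf-8") as handle:
            for rec in csv.DictReader(handle, delimiter="\t"):
                allowed.setdefault(rec["column"], set()).add(rec["term"])
        return cls(columns, allowed, vocabulary.load_default_registries())


_DEFAULT_SCHEMA: Schema | None = None


def default_schema() -> Schema:
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        _DEFAULT_SCHEMA = Schema.default()
    return _DEFAULT_SCHEMA


@dataclass
class ReduRecord:
    """One harmonized row: one raw file with its controlled metadata."""

    mri: MsRunIdentifier
    fields: dict[str, str] = field(default_factory=dict)

    @property
    def source_repository(self) -> str:
        return self.mri.repository.name

    def get(self, column: str) -> str | None:
        return self.fields.get(column)


@dataclass
class Rejection:
    """Why a candidate did not enter the table."""

    mri: str
    reason: str


def accept_record(candidate: dict[str, str], schema: Schema | None = None) -> ReduRecord | Rejection:
    """Apply the minimum-metadata acceptance rule to a candidate field map.

    The candidate must carry a valid ``MRI`` entry (a malformed one raises
    — that is a structural error, not a metadata rejection). It is accepted
    iff at least one sample-descriptive field (organism, body part, or
    sample type — blanks/QCs included) is populated with a real value.
    """
    schema = schema or default_schema()
    mri_text = candidate.get("MRI", "")
    mri = mri_text if isinstance(mri_text, MsRunIdentifier) else parse_mri(mri_text)

    fields = {}
    for key, value in candidate.items():
        if key in ("MRI", "SourceRepository"):
            continue
        if value is None:
            continue
        value = str(value).strip()
        if value and value != MISSING:
            fields[key] = value

    if not any(f in fields for f in DESCRIPTIVE_FIELDS):
        return Rejection(
            format_mri(mri),
            "no sample-descriptive metadata: requires at least one of "
            + ", ".join(DESCRIPTIVE_FIELDS),
        )
    return ReduRecord(mri=mri, fields=fields)


@dataclass
class ReduTable:
    records: list[ReduRecord] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)  # mri string → source ids

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ValidationFailure:
    mri: str
    column: str
    value: str
    message: str


@dataclass
class ValidationReport:
    failures: list[ValidationFailure] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_table(table: ReduTable, schema: Schema | None = None) -> ValidationReport:
    """Check every populated cell against its column's registry.

    Reports duplicate MRIs, unknown columns, vocabulary violations, and
    malformed taxonomy/year/coordinate values — every failure with the row
    key, column, and offending value.
    """
    schema = schema or default_schema()
    report = ValidationReport()
    seen: set[str] = set()
    for record in table.records:
        key = format_mri(record.mri)
        if key in seen:
            report.failures.append(ValidationFailure(key, "MRI", key, "duplicate MRI"))
        seen.add(key)
        for column, value in record.fields.items():
            message = schema.check_value(column, value)
            if message is not None:
                report.failures.append(ValidationFailure(key, column, value, message))
    return report


def write_table(table: ReduTable, destination, schema: Schema | None = None) -> None:
    """Serialize to TSV with deterministic column order and explicit fillers.

    Refuses a table that does not validate; ``read_table`` inverts this
    exactly (round-trip identity, missing cells included).
    """
    schema = schema or default_schema()
    report = validate_table(table, schema)
    if not report.ok:
        first = report.failures[0]
        raise ValueError(
            f"table failed validation ({len(report.failures)} failures; first: "
            f"{first.mri} {first.column}={first.value!r}: {first.message})"
        )
    rows = []
    for record in table.records:
        key = format_mri(record.mri)
        row = {}
        for column in schema.column_order:
            if column == "MRI":
                row[column] = key
            elif column == "SourceRepository":
                row[column] = record.source_repository
            elif column == "ProvenanceIdentifiers":
                row[column] = table.provenance.get(key, record.fields.get(column, MISSING))
            else:
                row[column] = record.fields.get(column, MISSING)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=schema.column_order)
    frame.to_csv(destination, sep="\t", index=False, lineterminator="\n")


def read_table(source, schema: Schema | None = None) -> ReduTable:
    """Read a harmonized TSV back into records (inverse of write_table)."""
    schema = schema or default_schema()
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    table = ReduTable()
    for _, row in frame.iterrows():
        mri = parse_mri(row["MRI"])
        fields = {}
        for column in frame.columns:
            if column in ("MRI", "SourceRepository", "ProvenanceIdentifiers"):
                continue
            value = row[column]
            if value and value != MISSING:
                fields[column] = value
        provenance = row.get("ProvenanceIdentifiers", MISSING)
        if provenance and provenance != MISSING:
            table.provenance[row["MRI"]] = provenance
        table.records.append(ReduRecord(mri=mri, fields=fields))
    return table


#: Header mapping for SDRF export (sample characteristics + comments).
SDRF_COLUMN_MAP = {
    "NCBITaxonomy": "characteristics[organism]",
    "UBERONBodyPartName": "characteristics[organism part]",
    "BiologicalSex": "characteristics[sex]",
    "AgeInYears": "characteristics[age]",
    "DOIDCommonName": "characteristics[disease]",
    "MassSpectrometer": "comment[instrument]",
    "ChromatographyAndPhase": "comment[chromatography]",
}


def write_sdrf(table: ReduTable, destination, schema: Schema | None = None) -> None:
    """Export the table under SDRF-style headers (header mapping only)."""
    rows = []
    for record in table.records:
        row = {"source name": format_mri(record.mri),
               "comment[data file]": record.mri.run_path}
        for column, header in SDRF_COLUMN_MAP.items():
            row[header] = record.fields.get(column, "not available")
        rows.append(row)
    columns = ["source name", "comment[data file]"] + list(SDRF_COLUMN_MAP.values())
    pd.DataFrame(rows, columns=columns).to_csv(destination, sep="\t", index=False, lineterminator="\n")
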