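"""ISA-Tab study reader and MetaboLights → ReDU column mapping.

MetaboLights organizes each study as an Investigation/Study/Assay (ISA)
folder: one ``i_*.txt`` investigation file (vertical key/value blocks),
one or more ``s_*.txt`` sample tables and ``a_*.txt`` assay tables, all
tab-delimited with quoted fields. Column headers repeat — every ontology-
annotated column is followed by ``Term Source REF`` / ``Term Accession
Number`` — so tables are kept positional rather than name-keyed.

Column mapping joins each raw-file-bearing assay row with its sample row
and translates MetaboLights column names to the harmonized schema, e.g.
``Organism`` → NCBITaxonomy, ``Organism part`` → UBERONBodyPartName,
``Instrument`` → MassSpectrometer. Where no predefined column exists the
mapper falls back to submitter-named factor/characteristic columns
(``Factor Value[sex]``, ``Characteristics[gender]``, ...).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .identifiers import OPEN_EXTENSIONS, VENDOR_EXTENSIONS

_TAXON_ACCESSION = re.compile(r"NCBITaxon(?:_|:|%3A)?(\d+)$", re.IGNORECASE)

#: Assay columns that carry raw data file names, in preference order.
RAW_FILE_COLUMNS = (
    "Raw Spectral Data File",
    "Acquisition Parameter Data File",
    "Derived Spectral Data File",
)


class IsaTabError(ValueError):
    """Structural problem with an ISA-Tab study folder."""


@dataclass
class IsaTable:
    """A tab-delimited ISA table with possibly duplicated headers."""

    columns: list[str]
    rows: list[list[str]]
    source_name: str = ""
    warnings: list[str] = field(default_factory=list)

    def column_index(self, name: str) -> int | None:
        """First index of an exactly (case-insensitively) named column."""
        target = name.strip().lower()
        for i, col in enumerate(self.columns):
            if col.strip().lower() == target:
                return i
        return None

    def find_column(self, inner_term: str) -> int | None:
        """Index of a column matching the bare term or a
        ``Factor Value[term]`` / ``Characteristics[term]`` /
        ``Parameter Value[term]`` wrapper, case-insensitive on the term."""
        target = inner_term.strip().lower()
        for i, col in enumerate(self.columns):
            name = col.strip().lower()
            if name == target:
                return i
            m = re.fullmatch(r"(factor value|characteristics|parameter value|comment)\[(.+)\]", name)
            if m and m.group(2).strip() == target:
                return i
        return None

    def value(self, row: list[str], index: int) -> str:
        return row[index].strip() if index < len(row) else ""

    def ontology_triplet(self, row: list[str], index: int) -> tuple[str, str, str]:
        """(term, source, accession) for an ontology-annotated column.

        The annotation columns, when present, immediately follow the parent
        column; absent annotations come back as empty strings.
        """
        term = self.value(row, index)
        source = accession = ""
        if index + 1 < len(self.columns) and self.columns[index + 1].strip().lower() == "term source ref":
            source = self.value(row, index + 1)
        if index + 2 < len(self.columns) and self.columns[index + 2].strip().lower() == "term accession number":
            accession = self.value(row, index + 2)
        return term, source, accession


@dataclass
class IsaStudy:
    study_id: str
    sample_table: IsaTable
    assay_tables: list[IsaTable]
    investigation_fields: dict[str, str] = field(default_factory=dict)
    orphaned: list[tuple[int, int, str]] = field(default_factory=list)  # (assay idx, row idx, sample)

    def sample_row(self, sample_name: str) -> list[str] | None:
        idx = self.sample_table.column_index("Sample Name")
        if idx is None:
            return None
        for row in self.sample_table.rows:
            if self.sample_table.value(row, idx) == sample_name:
                return row
        return None


def _read_table(path: Path) -> IsaTable:
    with open(path, encoding="utf-8", errors="replace", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t", quotechar='"')
        rows = [row for row in reader]
    if not rows:
        raise IsaTabError(f"{path.name}: empty table")
    columns = [c.strip() for c in rows[0]]
    table = IsaTable(columns=columns, rows=[], source_name=path.name)
    width = len(columns)
    for i, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != width:
            table.warnings.append(f"{path.name} line {i}: ragged row padded/truncated")
            row = (row + [""] * width)[:width]
        table.rows.append(row)
    return table


def _read_investigation(path: Path) -> dict[str, str]:
    """Investigation file: vertical blocks, first cell is the key."""
    fields: dict[str, str] = {}
    with open(path, encoding="utf-8", errors="replace", newline="") as handle:
        for row in csv.reader(handle, delimiter="\t", quotechar='"'):
            if not row or not row[0].strip() or row[0].startswith(("ONTOLOGY", "#")):
                continue
            key = row[0].strip()
            values = [c.strip() for c in row[1:] if c.strip()]
            if values and key not in fields:
                fields[key] = values[0]
    return fields


def parse_isatab(folder) -> IsaStudy:
    """Load an ISA-Tab study folder into linked tables.

    Requires ``i_*.txt`` plus at least one ``s_*.txt`` and one ``a_*.txt``;
    assay rows naming a sample absent from the sample table are flagged
    orphaned (never dropped silently).
    """
    folder = Path(folder)
    inv_files = sorted(folder.glob("i_*.txt"))
    sample_files = sorted(folder.glob("s_*.txt"))
    assay_files = sorted(folder.glob("a_*.txt"))
    if not sample_files:
        raise IsaTabError(f"{folder}: no s_*.txt sample table found")
    if not assay_files:
        raise IsaTabError(f"{folder}: no a_*.txt assay table found")

    investigation = _read_investigation(inv_files[0]) if inv_files else {}
    study_id = investigation.get("Study Identifier", folder.name)
    sample_table = _read_table(sample_files[0])
    assay_tables = [_read_table(p) for p in assay_files]

    study = IsaStudy(study_id=study_id, sample_table=sample_table,
                     assay_tables=assay_tables, investigation_fields=investigation)

    name_idx = sample_table.column_index("Sample Name")
    known = set()
    if name_idx is not None:
        known = {sample_table.value(r, name_idx) for r in sample_table.rows}
    for ti, assay in enumerate(assay_tables):
        a_idx = assay.column_index("Sample Name")
        if a_idx is None:
            continue
        for ri, row in enumerate(assay.rows):
            sample = assay.value(row, a_idx)
            if sample and sample not in known:
                study.orphaned.append((ti, ri, sample))
    return study


@dataclass(frozen=True)
class ColumnEquivalence:
    """How one harmonized column is sourced from MetaboLights columns."""

    redu_column: str
    primary_source: str | None = None
    fallback_sources: tuple[str, ...] = ()


#: The shipped registry: the documented primary mappings plus common
#: submitter-named fallbacks. User registries (TSV) merge over these.
DEFAULT_EQUIVALENCES: tuple[ColumnEquivalence, ...] = (
    ColumnEquivalence("NCBITaxonomy", "Organism", ("organism", "species")),
    ColumnEquivalence("UBERONBodyPartName", "Organism part", ("organism part", "tissue", "body part")),
    ColumnEquivalence("MassSpectrometer", "Instrument", ("instrument", "mass spectrometer")),
    ColumnEquivalence("BiologicalSex", None, ("sex", "gender")),
    ColumnEquivalence("DOIDCommonName", "Disease", ("disease", "diagnosis")),
    ColumnEquivalence("SampleType", "Sample type", ("sample type", "material type")),
    ColumnEquivalence("ChromatographyAndPhase", "Column type", ("column type", "chromatography")),
    ColumnEquivalence("AgeInYears", None, ("age",)),
)


def load_equivalences(path) -> tuple[ColumnEquivalence, ...]:
    """Read a user equivalence registry: TSV with columns
    ``redu_column``, ``primary_source``, ``fallback_sources`` (pipe-joined)."""
    out = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for rec in reader:
            fallbacks = tuple(s.strip() for s in (rec.get("fallback_sources") or "").split("|") if s.strip())
            out.append(ColumnEquivalence(rec["redu_column"].strip(),
                                         (rec.get("primary_source") or "").strip() or None,
                                         fallbacks))
    return tuple(out)


def _taxid_from_accession(accession: str) -> int | None:
    m = _TAXON_ACCESSION.search(accession)
    return int(m.group(1)) if m else None


def _lookup(table: IsaTable, row: list[str], equivalence: ColumnEquivalence) -> tuple[str, str] | None:
    """Resolve one equivalence against one row; returns (term, accession)."""
    if equivalence.primary_source:
        idx = table.find_column(equivalence.primary_source)
        if idx is not None:
            term, _src, acc = table.ontology_triplet(row, idx)
            if term:
                return term, acc
    for name in equivalence.fallback_sources:
        idx = table.find_column(name)
        if idx is not None:
            term, _src, acc = table.ontology_triplet(row, idx)
            if term:
                return term, acc
    return None


def map_columns(
    study: IsaStudy,
    equivalences: tuple[ColumnEquivalence, ...] = DEFAULT_EQUIVALENCES,
) -> dict[str, dict[str, str]]:
    """Map each raw file named in the assay tables to partial ReDU fields.

    Sample-level and assay-level columns are joined per row; the primary
    source wins over fallbacks; absent values leave the field unset (never
    the empty string). Taxonomy rows with a resolvable NCBITaxon accession
    are emitted directly in ``taxid|name`` form.
    """
    if not equivalences:
        raise ValueError("empty equivalence registry")
    out: dict[str, dict[str, str]] = {}
    for assay in study.assay_tables:
        file_idx = None
        for col in RAW_FILE_COLUMNS:
            file_idx = assay.column_index(col)
            if file_idx is not None:
                break
        if file_idx is None:
            continue
        sample_idx = assay.column_index("Sample Name")
        for row in assay.rows:
            raw_file = assay.value(row, file_idx)
            if not raw_file:
                continue
            fields: dict[str, str] = {}
            sample_row = None
            if sample_idx is not None:
                sample_row = study.sample_row(assay.value(row, sample_idx))
            for eq in equivalences:
                hit = None
                if sample_row is not None:
                    hit = _lookup(study.sample_table, sample_row, eq)
                if hit is None:
                    hit = _lookup(assay, row, eq)
                if hit is None:
                    continue
                term, accession = hit
                if eq.redu_column == "NCBITaxonomy" and accession:
                    taxid = _taxid_from_accession(accession)
                    if taxid is not None:
                        term = f"{taxid}|{term}"
                fields[eq.redu_column] = term
            out[raw_file] = fields
    return out


def prefer_open_format(files: list[str]) -> list[str]:
    """Keep only the open copy when a run was deposited in several formats.

    Files sharing a base name modulo one extension (case-insensitive) are
    treated as the same run; when the group holds an open-format copy
    (mzML/mzXML) the vendor copies are removed. Files without an open
    sibling are never touched, and the pass is idempotent.
    """
    def stem(path: str) -> str:
        name = path.rsplit("/", 1)[-1]
        return (name.rsplit(".", 1)[0] if "." in name else name).lower()

    def ext(path: str) -> str:
        name = path.rsplit("/", 1)[-1]
        return name.rsplit(".", 1)[-1].lower() if "." in name else ""

    open_stems = {stem(f) for f in files if ext(f) in OPEN_EXTENSIONS}
    return [f for f in files
            if not (ext(f) in VENDOR_EXTENSIONS and stem(f) in open_stems)]
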