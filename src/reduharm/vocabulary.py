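"""Controlled-vocabulary translation: sheets, ontology registries, taxonomy.

Free-text or repository-controlled terms are converted to the harmonized
vocabulary through three layers, tried in order:

1. *exact* translation-sheet entries (curated term → controlled term),
2. flat ontology registries (canonical terms and synonyms for body parts,
   plant parts, cell types, diseases, instruments, and taxa),
3. *substring* translation-sheet entries (curated pattern contained in the
   free text), longest pattern winning ties.

A term that survives none of the layers comes back as an explicit
:class:`Unmapped` marker — never a silent pass-through — and the pipeline
exports unmapped terms to a review sheet for manual curation.

Registries and sheets are flat TSV snapshots packaged with the module;
user-supplied sheets merge over (take precedence before) the packaged ones.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

_MIN_SUBSTRING_PATTERN = 3  # shorter substring patterns cause false hits
_TAXONOMY_FORM = re.compile(r"\d+\|.+")


class Unmapped(NamedTuple):
    """Marker for a term no layer could resolve."""

    raw: str
    column: str


@dataclass(frozen=True)
class SheetEntry:
    source_pattern: str
    match_mode: str  # "exact" | "substring"
    target_term: str
    target_column: str


@dataclass
class TranslationSheet:
    """Ordered collection of curated term mappings."""

    entries: list[SheetEntry] = field(default_factory=list)

    def for_column(self, column: str, mode: str) -> list[SheetEntry]:
        return [e for e in self.entries if e.target_column == column and e.match_mode == mode]

    @classmethod
    def from_tsv(cls, path) -> "TranslationSheet":
        entries = []
        with open(path, encoding="utf-8", newline="") as handle:
            for rec in csv.DictReader(handle, delimiter="\t"):
                mode = rec["match_mode"].strip().lower()
                if mode not in ("exact", "substring"):
                    raise ValueError(f"unknown match_mode {mode!r} in {path}")
                entries.append(SheetEntry(rec["source_pattern"].strip(), mode,
                                          rec["target_term"].strip(), rec["target_column"].strip()))
        return cls(entries)

    def merged_over(self, base: "TranslationSheet") -> "TranslationSheet":
        """This sheet's entries first, then the base's (user over packaged)."""
        return TranslationSheet(self.entries + base.entries)


@dataclass
class OntologyRecord:
    term: str
    identifier: str
    synonyms: tuple[str, ...] = ()


@dataclass
class OntologyRegistry:
    """Flat term ↔ identifier ↔ synonyms lookup for one domain."""

    domain: str
    records: list[OntologyRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, OntologyRecord] = {}
        for rec in self.records:
            self._index.setdefault(rec.term.lower(), rec)
            for syn in rec.synonyms:
                self._index.setdefault(syn.lower(), rec)

    def lookup(self, raw: str) -> OntologyRecord | None:
        """Case-insensitive canonical/synonym lookup."""
        return self._index.get(_normalize(raw).lower())

    def terms(self) -> list[str]:
        return [rec.term for rec in self.records]

    @classmethod
    def from_tsv(cls, domain: str, path) -> "OntologyRegistry":
        records = []
        with open(path, encoding="utf-8", newline="") as handle:
            for rec in csv.DictReader(handle, delimiter="\t"):
                synonyms = tuple(s.strip() for s in (rec.get("synonyms") or "").split("|") if s.strip())
                records.append(OntologyRecord(rec["term"].strip(), rec["identifier"].strip(), synonyms))
        return cls(domain, records)


#: Which ontology domains feed which harmonized column.
COLUMN_DOMAINS: dict[str, tuple[str, ...]] = {
    "NCBITaxonomy": ("taxonomy",),
    "UBERONBodyPartName": ("body_part", "plant_part", "cell_type"),
    "DOIDCommonName": ("disease",),
    "MassSpectrometer": ("instrument",),
}

_ONTOLOGY_FILES = {
    "taxonomy": "ontology_taxonomy.tsv",
    "body_part": "ontology_body_part.tsv",
    "plant_part": "ontology_plant_part.tsv",
    "cell_type": "ontology_cell_type.tsv",
    "disease": "ontology_disease.tsv",
    "instrument": "ontology_instrument.tsv",
}


def _data_path(name: str):
    return resources.files("reduharm.data") / name


def load_default_registries() -> dict[str, OntologyRegistry]:
    return {domain: OntologyRegistry.from_tsv(domain, _data_path(fname))
            for domain, fname in _ONTOLOGY_FILES.items()}


def load_default_sheet() -> TranslationSheet:
    return TranslationSheet.from_tsv(_data_path("translations.tsv"))


def _normalize(raw: str) -> str:
    return " ".join(raw.split())


def format_taxonomy(taxid: int, name: str) -> str:
    """Render the harmonized taxonomy term, e.g. ``9606|Homo sapiens``."""
    if taxid <= 0:
        raise ValueError(f"taxid must be positive, got {taxid}")
    if not name.strip():
        raise ValueError("taxon name must be non-empty")
    return f"{taxid}|{name.strip()}"


def translate_term(
    raw: str,
    column: str,
    sheet: TranslationSheet,
    registries: dict[str, OntologyRegistry],
) -> str | Unmapped:
    """Resolve one free-text value for one harmonized column.

    Pure in its inputs: shuffling sheet row order never changes the result
    (exact before substring; among substring hits the longest pattern wins,
    ties broken by lexicographic pattern order).
    """
    text = _normalize(raw)
    if not text:
        raise ValueError("raw term empty after whitespace normalization")
    lowered = text.lower()

    # Already in harmonized taxid|name form: accept verbatim.
    if column == "NCBITaxonomy" and _TAXONOMY_FORM.fullmatch(text):
        return text

    exact = [e for e in sheet.for_column(column, "exact")
             if _normalize(e.source_pattern).lower() == lowered]
    if exact:
        return min(exact, key=lambda e: e.target_term).target_term

    for domain in COLUMN_DOMAINS.get(column, ()):
        registry = registries.get(domain)
        if registry is None:
            continue
        rec = registry.lookup(text)
        if rec is not None:
            if column == "NCBITaxonomy":
                return format_taxonomy(int(rec.identifier), rec.term)
            return rec.term

    hits = [e for e in sheet.for_column(column, "substring")
            if len(e.source_pattern) >= _MIN_SUBSTRING_PATTERN
            and _normalize(e.source_pattern).lower() in lowered]
    if hits:
        best = min(hits, key=lambda e: (-len(e.source_pattern), e.source_pattern))
        return best.target_term

    return Unmapped(raw=text, column=column)


def write_unmapped_report(unmapped: list[Unmapped], path) -> None:
    """Export unresolved terms for manual curation (deduplicated, sorted)."""
    rows = sorted({(u.column, u.raw) for u in unmapped})
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["column", "raw_term", "occurrences"])
        counts: dict[tuple[str, str], int] = {}
        for u in unmapped:
            counts[(u.column, u.raw)] = counts.get((u.column, u.raw), 0) + 1
        for column, raw in rows:
            writer.writerow([column, raw, counts[(column, raw)]])
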