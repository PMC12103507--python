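"""End-to-end harmonization: study folders in, one validated table out.

Orchestrates the whole flow for a root directory of study folders, one per
dataset accession:

* dialect detection (mwTab documents → NMDR, ``i_*.txt``/``s_*.txt``/
  ``a_*.txt`` → MetaboLights ISA-Tab, a ``redu_metadata.tsv`` → native
  controlled table),
* per-dialect ingestion and term translation,
* the file↔sample linkage cascade with polarity disambiguation for
  multi-analysis studies,
* the minimum-metadata acceptance rule and table validation.

Every discard decision — ambiguous file, dropped analysis metadata,
rejected candidate, discarded study — is written to a structured
JSON-lines log so harmonization runs stay auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import linker, msdata, mtbls_ingest, mwtab_ingest, redu_schema, vocabulary
from .identifiers import has_supported_extension, make_mri
from .polarity import Polarity

_YEAR = re.compile(r"(19|20)\d{2}")

#: mwTab slots harmonized at the sample level (consistent across analyses).
_SAMPLE_LEVEL_SLOTS = (
    ("SUBJECT", "SUBJECT_SPECIES", "NCBITaxonomy"),
    ("COLLECTION", "SAMPLE_TYPE", "UBERONBodyPartName"),
    ("SUBJECT", "GENDER", "BiologicalSex"),
)
#: mwTab slots valid only for the analysis a file was assigned to.
_ANALYSIS_LEVEL_SLOTS = (
    ("MS", "INSTRUMENT_NAME", "MassSpectrometer"),
    ("CHROMATOGRAPHY", "CHROMATOGRAPHY_TYPE", "ChromatographyAndPhase"),
)

_ION_SOURCES = {"esi": "electrospray ionization",
                "apci": "atmospheric pressure chemical ionization"}


@dataclass
class StudyResult:
    accession: str
    dialect: str
    linkage: linker.StudyLinkage | None = None
    records: list[redu_schema.ReduRecord] = field(default_factory=list)
    rejections: list[redu_schema.Rejection] = field(default_factory=list)
    unmapped: list[vocabulary.Unmapped] = field(default_factory=list)
    dropped_analysis_files: list[str] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    @property
    def discarded(self) -> bool:
        return not self.records

    def note(self, event: str, **details) -> None:
        entry = {"study": self.accession, "event": event}
        entry.update(details)
        self.log.append(entry)


@dataclass
class HarmonizationResult:
    table: redu_schema.ReduTable
    studies: list[StudyResult]

    @property
    def log(self) -> list[dict]:
        out = []
        for study in self.studies:
            out.extend(study.log)
        return out


def detect_dialect(folder: Path) -> str | None:
    if any(folder.glob("*.mwtab")):
        return "NMDR"
    if any(folder.glob("s_*.txt")) and any(folder.glob("a_*.txt")):
        return "MTBLS"
    if (folder / "redu_metadata.tsv").is_file():
        return "GNPS/MassIVE"
    return None


def _list_raw_files(folder: Path) -> list[str]:
    """Deposited raw files, as study-relative slash paths, sorted."""
    out = []
    for path in sorted(folder.rglob("*")):
        if path.is_file() and has_supported_extension(path.name):
            out.append(path.relative_to(folder).as_posix())
    return out


def _translate(
    raw: str, column: str, sheet, registries, study: StudyResult
) -> str | None:
    if not raw or not raw.strip():
        return None
    result = vocabulary.translate_term(raw, column, sheet, registries)
    if isinstance(result, vocabulary.Unmapped):
        study.unmapped.append(result)
        return None
    return result


def _ionization_term(ms_type: str, polarity: Polarity) -> str | None:
    source = _ION_SOURCES.get(ms_type.strip().lower())
    if source is None:
        return None
    suffix = {Polarity.POSITIVE: " (positive)", Polarity.NEGATIVE: " (negative)"}
    return source + suffix.get(polarity, "")


def _year_from(doc: mwtab_ingest.MwTabDocument) -> str | None:
    for section, key in (("PROJECT", "PROJECT_DATE"), ("STUDY", "SUBMIT_DATE")):
        value = doc.sections.get(section, {}).get(key, "")
        match = _YEAR.search(value)
        if match:
            return match.group(0)
    return None


def _finish_candidate(
    study: StudyResult, candidate: dict[str, str], provenance: str,
    table: redu_schema.ReduTable, schema,
) -> None:
    outcome = redu_schema.accept_record(candidate, schema)
    if isinstance(outcome, redu_schema.Rejection):
        study.rejections.append(outcome)
        study.note("record_rejected", mri=outcome.mri, reason=outcome.reason)
        return
    study.records.append(outcome)
    table.records.append(outcome)
    table.provenance[redu_schema.format_mri(outcome.mri)] = provenance


# ---------------------------------------------------------------------------
# Dialect handlers


def _harmonize_nmdr(folder: Path, study: StudyResult, sheet, registries,
                    schema, table, separators) -> None:
    docs = [mwtab_ingest.read_mwtab(p) for p in sorted(folder.glob("*.mwtab"))]
    files = _list_raw_files(folder)
    if not files:
        study.note("study_discarded", reason="no raw files deposited")
        return

    descriptors: dict[str, list[str]] = {}
    for doc in docs:
        for sample_id, values in mwtab_ingest.extract_sample_descriptors(doc).items():
            merged = descriptors.setdefault(sample_id, [])
            for value in values:
                if value not in merged:
                    merged.append(value)

    study.linkage = linker.associate_files(files, descriptors, separators)
    for result in study.linkage.ambiguous:
        study.note("file_ambiguous", run_path=result.run_path, tier=result.tier.value)
    if study.linkage.discarded_study:
        study.note("study_discarded",
                   reason="no spectral data could be associated with specific samples")
        return

    summaries: list[tuple[str, msdata.ScanSummary]] = []
    for run_path in files:
        try:
            summaries.append((run_path, msdata.summarize_scans(folder / run_path, run_path)))
        except msdata.IntegrityError:
            study.note("scan_summary_failed", run_path=run_path)
    assignment = linker.disambiguate_by_polarity(docs, summaries) if docs else {}
    docs_by_id = {doc.analysis_id: doc for doc in docs}

    # Sample-level fields must be consistent across all analyses to be used.
    sample_fields: dict[str, str] = {}
    for section, key, column in _SAMPLE_LEVEL_SLOTS:
        values = {doc.sections.get(section, {}).get(key, "").strip() for doc in docs}
        values.discard("")
        if len(values) == 1:
            term = _translate(values.pop(), column, sheet, registries, study)
            if term:
                sample_fields[column] = term
    if "SampleType" not in sample_fields and (
            "NCBITaxonomy" in sample_fields or "UBERONBodyPartName" in sample_fields):
        sample_fields["SampleType"] = "biological"

    for link in study.linkage.accepted:
        candidate: dict[str, str] = dict(sample_fields)
        candidate["MRI"] = f"mzspec:{study.accession}:{link.run_path}"
        assigned = assignment.get(link.run_path)
        if assigned is None and len(docs) > 1:
            study.dropped_analysis_files.append(link.run_path)
            study.note("analysis_metadata_dropped", run_path=link.run_path,
                       reason="polarity could not single out one analysis")
        if assigned is not None:
            doc = docs_by_id[assigned]
            for section, key, column in _ANALYSIS_LEVEL_SLOTS:
                raw = doc.sections.get(section, {}).get(key, "")
                term = _translate(raw, column, sheet, registries, study) if raw else None
                if term:
                    candidate[column] = term
            ion = _ionization_term(doc.sections.get("MS", {}).get("MS_TYPE", ""), doc.polarity)
            if ion:
                candidate["IonizationSourceAndPolarity"] = ion
            year = _year_from(doc)
            if year:
                candidate["YearOfAnalysis"] = year
        provenance = assigned or ";".join(sorted(docs_by_id))
        _finish_candidate(study, candidate, provenance, table, schema)


def _harmonize_mtbls(folder: Path, study: StudyResult, sheet, registries,
                     schema, table) -> None:
    isa = mtbls_ingest.parse_isatab(folder)
    study.accession = isa.study_id or study.accession
    field_maps = mtbls_ingest.map_columns(isa)
    deposited = list(field_maps)
    kept = mtbls_ingest.prefer_open_format(deposited)
    for dropped in set(deposited) - set(kept):
        study.note("vendor_duplicate_dropped", run_path=dropped)

    for run_path in kept:
        raw_fields = field_maps[run_path]
        candidate: dict[str, str] = {"MRI": f"mzspec:{study.accession}:{run_path}"}
        for column, raw in raw_fields.items():
            term = _translate(raw, column, sheet, registries, study)
            if term:
                candidate[column] = term
        if "SampleType" not in candidate and (
                "NCBITaxonomy" in candidate or "UBERONBodyPartName" in candidate):
            candidate["SampleType"] = "biological"
        _finish_candidate(study, candidate, isa.study_id, table, schema)


def _harmonize_native(folder: Path, study: StudyResult, sheet, registries,
                      schema, table) -> None:
    import csv as _csv

    with open(folder / "redu_metadata.tsv", encoding="utf-8", newline="") as handle:
        reader = _csv.DictReader(handle, delimiter="\t")
        for row in reader:
            run_path = (row.get("filename") or "").strip()
            if not run_path:
                continue
            candidate: dict[str, str] = {"MRI": f"mzspec:{study.accession}:{run_path}"}
            for column, raw in row.items():
                if column == "filename" or not raw or not raw.strip():
                    continue
                kind = schema.by_name.get(column)
                raw = raw.strip()
                if kind is not None and kind.kind in ("vocab", "taxonomy"):
                    term = raw if schema.check_value(column, raw) is None else None
                    if term is None:
                        term = _translate(raw, column, sheet, registries, study)
                    if term:
                        candidate[column] = term
                else:
                    candidate[column] = raw
            _finish_candidate(study, candidate, study.accession, table, schema)


# ---------------------------------------------------------------------------
# Entry points


def harmonize_root(
    root,
    sheet: vocabulary.TranslationSheet | None = None,
    registries: dict[str, vocabulary.OntologyRegistry] | None = None,
    schema: redu_schema.Schema | None = None,
    separators: tuple[str, ...] = linker.DEFAULT_SEPARATORS,
) -> HarmonizationResult:
    """Harmonize every recognizable study folder under ``root``.

    Folders are processed in sorted order; the run is fully deterministic
    for a fixed input tree.
    """
    root = Path(root)
    sheet = sheet or vocabulary.load_default_sheet()
    registries = registries or vocabulary.load_default_registries()
    schema = schema or redu_schema.default_schema()
    table = redu_schema.ReduTable()
    studies: list[StudyResult] = []

    for folder in sorted(p for p in root.iterdir() if p.is_dir()):
        dialect = detect_dialect(folder)
        if dialect is None:
            continue
        study = StudyResult(accession=folder.name, dialect=dialect)
        study.note("study_started", dialect=dialect)
        if dialect == "NMDR":
            _harmonize_nmdr(folder, study, sheet, registries, schema, table, separators)
        elif dialect == "MTBLS":
            _harmonize_mtbls(folder, study, sheet, registries, schema, table)
        else:
            _harmonize_native(folder, study, sheet, registries, schema, table)
        if study.discarded:
            study.note("study_discarded", reason="no record passed the "
                       "minimum sample-descriptive metadata rule")
        studies.append(study)
    return HarmonizationResult(table=table, studies=studies)


def write_outputs(result: HarmonizationResult, out_dir) -> dict[str, Path]:
    """Write the table, linkage report, unmapped-term review sheet, and log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "redu_table.tsv",
        "linkage": out / "linkage_report.tsv",
        "unmapped": out / "unmapped_terms.tsv",
        "log": out / "harmonization_log.jsonl",
    }
    redu_schema.write_table(result.table, paths["table"])

    import csv as _csv
    with open(paths["linkage"], "w", encoding="utf-8", newline="") as handle:
        writer = _csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["study", "run_path", "sample_id", "tier", "status"])
        for study in result.studies:
            if study.linkage is None:
                continue
            for res in study.linkage.accepted:
                writer.writerow([study.accession, res.run_path, res.sample_id,
                                 res.tier.value, "accepted"])
            for res in study.linkage.ambiguous:
                writer.writerow([study.accession, res.run_path, "", res.tier.value, "ambiguous"])
            for run_path in study.linkage.unlinked_files:
                writer.writerow([study.accession, run_path, "", "", "unlinked"])

    unmapped = [u for study in result.studies for u in study.unmapped]
    vocabulary.write_unmapped_report(unmapped, paths["unmapped"])

    with open(paths["log"], "w", encoding="utf-8") as handle:
        for entry in result.log:
            handle.write(json.dumps(entry, sort_keys=True) + "\n")
    return paths


def query_table(table: redu_schema.ReduTable, filters: dict[str, str]) -> list[str]:
    """Conjunctive exact-match filtering; returns MRIs in table order."""
    schema = redu_schema.default_schema()
    for column in filters:
        if column not in schema.by_name:
            raise KeyError(f"unknown column {column!r}")
    out = []
    for record in table.records:
        row = dict(record.fields)
        row["SourceRepository"] = record.source_repository
        if all(row.get(column) == value for column, value in filters.items()):
            out.append(redu_schema.format_mri(record.mri))
    return out
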