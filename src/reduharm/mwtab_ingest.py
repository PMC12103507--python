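"""Parser and writer for mwTab metadata documents (NMDR dialect).

mwTab is the line-oriented, sectioned key-value format of the Metabolomics
Workbench / National Metabolomics Data Repository: one document per
*analysis*, sections introduced by ``#SECTION`` headers, entries as either
TAB-delimited ``KEY<TAB>value`` or ``KEY:value`` lines (both occur in the
wild; the first delimiter on the line wins).

The ``SUBJECT_SAMPLE_FACTORS`` block is tabular, one row per sample:

    SUBJECT_SAMPLE_FACTORS <TAB> subject <TAB> sample_id <TAB> factors <TAB> additional

with ``factors`` as ``key:value | key:value`` pairs and ``additional`` as
``key=value | key=value`` pairs. Pairs are separated by ``|`` (never ``;``)
because raw-file descriptors legitimately contain ``;``-joined file lists
that must reach the record linker unsplit.

Only the metadata the harmonizer consumes is modelled; the quantitative
``#MS_METABOLITE_DATA`` matrices are carried verbatim but not interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .polarity import Polarity, parse_polarity_label

HEADER_PREFIX = "#METABOLOMICS WORKBENCH"
SSF_SECTION = "SUBJECT_SAMPLE_FACTORS"
PAIR_SEPARATOR = " | "


class MwTabParseError(ValueError):
    """The document is not recognizably mwTab (missing mandatory header)."""


@dataclass
class SampleFactorRow:
    """One sample's row of the SUBJECT_SAMPLE_FACTORS block."""

    sample_id: str
    subject_id: str = "-"
    factors: dict[str, str] = field(default_factory=dict)
    additional_data: dict[str, str] = field(default_factory=dict)


@dataclass
class MwTabDocument:
    """One parsed analysis: header ids, sections, per-sample factor rows."""

    analysis_id: str
    study_id: str = ""
    sections: dict[str, dict[str, str]] = field(default_factory=dict)
    subject_sample_factors: list[SampleFactorRow] = field(default_factory=list)
    header_line: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def polarity(self) -> Polarity:
        """Ion mode declared in the MS section, or UNSPECIFIED."""
        ms = self.sections.get("MS", {})
        for key in ("MS:ION_MODE", "ION_MODE"):
            if key in ms:
                return parse_polarity_label(ms[key])
        return Polarity.UNSPECIFIED


def _split_pairs(text: str, sep: str) -> dict[str, str]:
    """Parse ``k<sep>v | k<sep>v``; malformed fragments are skipped."""
    out: dict[str, str] = {}
    for chunk in text.split("|"):
        chunk = chunk.strip()
        if not chunk or chunk == "-":
            continue
        if sep not in chunk:
            continue
        key, value = chunk.split(sep, 1)
        key, value = key.strip(), value.strip()
        if key:
            out[key] = value
    return out


def _parse_ssf_row(line: str) -> SampleFactorRow | None:
    fields = line.split("\t")
    # fields[0] is the literal SUBJECT_SAMPLE_FACTORS tag
    if len(fields) < 3:
        return None
    subject = fields[1].strip()
    sample_id = fields[2].strip()
    if not sample_id:
        return None
    factors = _split_pairs(fields[3], ":") if len(fields) > 3 else {}
    additional = _split_pairs(fields[4], "=") if len(fields) > 4 else {}
    return SampleFactorRow(sample_id=sample_id, subject_id=subject or "-",
                           factors=factors, additional_data=additional)


def parse_mwtab(text: str) -> MwTabDocument:
    """Parse one mwTab document.

    Unknown sections are preserved verbatim (forward compatibility);
    malformed key lines are recorded as warnings and skipped, never fatal.
    Raises :class:`MwTabParseError` when the mandatory
    ``#METABOLOMICS WORKBENCH`` header is absent.
    """
    lines = text.splitlines()
    header = next((ln for ln in lines if ln.startswith(HEADER_PREFIX)), None)
    if header is None:
        raise MwTabParseError("missing mandatory '#METABOLOMICS WORKBENCH' header section")

    doc = MwTabDocument(analysis_id="", header_line=header)
    for token in header.split():
        if token.startswith("ANALYSIS_ID:"):
            doc.analysis_id = token.split(":", 1)[1]
        elif token.startswith("STUDY_ID:"):
            doc.study_id = token.split(":", 1)[1]

    current: str | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(HEADER_PREFIX):
            continue
        if line.startswith("#"):
            current = line[1:].strip().split("\t")[0].split(" ")[0]
            doc.sections.setdefault(current, {})
            continue
        if current == SSF_SECTION or line.startswith(SSF_SECTION + "\t"):
            row = _parse_ssf_row(line)
            if row is not None:
                doc.subject_sample_factors.append(row)
            else:
                doc.warnings.append(f"line {lineno}: unparseable sample-factor row skipped")
            continue
        if current is None:
            doc.warnings.append(f"line {lineno}: content before first section skipped")
            continue
        # key/value entry: first delimiter (TAB preferred, then colon) wins
        if "\t" in line:
            key, value = line.split("\t", 1)
        elif ":" in line:
            key, value = line.split(":", 1)
        else:
            doc.warnings.append(f"line {lineno}: malformed key line skipped")
            continue
        doc.sections[current][key.strip()] = value.strip()
    return doc


def serialize_mwtab(doc: MwTabDocument) -> str:
    """Write a document back to mwTab text.

    Round-trips all key/value content and sample-factor rows in section
    order; comments and blank-line layout of the original are not kept.
    """
    out = [doc.header_line or _default_header(doc)]
    for section, entries in doc.sections.items():
        if section == SSF_SECTION:
            continue
        out.append(f"#{section}")
        for key, value in entries.items():
            out.append(f"{key}\t{value}")
    if doc.subject_sample_factors or SSF_SECTION in doc.sections:
        out.append(f"#{SSF_SECTION}")
        for row in doc.subject_sample_factors:
            factors = PAIR_SEPARATOR.join(f"{k}:{v}" for k, v in row.factors.items()) or "-"
            extra = PAIR_SEPARATOR.join(f"{k}={v}" for k, v in row.additional_data.items())
            fields = [SSF_SECTION, row.subject_id, row.sample_id, factors]
            if extra:
                fields.append(extra)
            out.append("\t".join(fields))
    out.append("#END")
    return "\n".join(out) + "\n"


def _default_header(doc: MwTabDocument) -> str:
    bits = [HEADER_PREFIX]
    if doc.study_id:
        bits.append(f"STUDY_ID:{doc.study_id}")
    if doc.analysis_id:
        bits.append(f"ANALYSIS_ID:{doc.analysis_id}")
    return " ".join(bits)


def read_mwtab(path) -> MwTabDocument:
    """Read a document from disk as UTF-8, falling back to latin-1."""
    raw = open(path, "rb").read()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return parse_mwtab(text)


def extract_sample_descriptors(
    doc: MwTabDocument,
    file_table: dict[str, list[str]] | None = None,
    file_name_keys: tuple[str, ...] = ("RAW_FILE_NAME", "RAW_DATA_FILE", "DATAFILE"),
) -> dict[str, list[str]]:
    """Gather per-sample candidate raw-file descriptors in cascade priority.

    Priority order: the repository's REST-provided file table (when the
    caller supplies one), then named raw-file keys in the additional sample
    data, remaining additional-data values, factor values, and finally the
    sample identifier itself. Multi-file values such as ``a.mzML;b.mzML``
    are retained unsplit — separator handling belongs to the linker.
    """
    descriptors: dict[str, list[str]] = {}
    for row in doc.subject_sample_factors:
        seen: list[str] = []

        def add(value: str) -> None:
            value = value.strip()
            if value and value != "-" and value not in seen:
                seen.append(value)

        if file_table:
            for value in file_table.get(row.sample_id, []):
                add(value)
        for key in file_name_keys:
            if key in row.additional_data:
                add(row.additional_data[key])
        for key, value in row.additional_data.items():
            if key not in file_name_keys:
                add(value)
        for value in row.factors.values():
            add(value)
        add(row.sample_id)
        descriptors[row.sample_id] = seen
    return descriptors
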