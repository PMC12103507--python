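"""Scan-header summaries and XML integrity checks for mzML/mzXML files.

Only the per-spectrum headers are touched (MS level, polarity); peak data
is never decoded. Each file collapses to a :class:`ScanSummary` — scan
counts keyed by (MS level, polarity) — which feeds two consumers: the
MS/MS availability statistics and the linker's polarity disambiguation.

Integrity of an mzML/mzXML file means well-formed XML with the expected
root element; the retrieval cache uses this as its cache-validity check.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree
from pyteomics import mzxml as _mzxml

from .polarity import Polarity


class IntegrityError(ValueError):
    """The file is not a readable mzML/mzXML document (truncated, not XML,
    or carrying an unexpected root element)."""


@dataclass
class ScanSummary:
    """Per-file scan tallies by (MS level, polarity)."""

    run_path: str
    counts: dict[tuple[int, Polarity], int] = field(default_factory=dict)

    @property
    def total_scans(self) -> int:
        return sum(self.counts.values())

    def add(self, ms_level: int, polarity: Polarity, n: int = 1) -> None:
        if ms_level < 1:
            raise ValueError(f"ms_level must be >= 1, got {ms_level}")
        key = (ms_level, polarity)
        self.counts[key] = self.counts.get(key, 0) + n


def has_msms(summary: ScanSummary) -> bool:
    """True iff the file contains any fragmentation (MS level >= 2) scans."""
    return any(level >= 2 and count > 0 for (level, _pol), count in summary.counts.items())


def _open_maybe_gzip(path: Path, mode: str = "rb"):
    if str(path).lower().endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _root_tag(path: Path) -> str:
    """Local name of the document's root element ('' when not XML)."""
    try:
        with _open_maybe_gzip(path) as handle:
            for _event, element in etree.iterparse(handle, events=("start",)):
                return etree.QName(element.tag).localname
    except (etree.XMLSyntaxError, OSError, ValueError):
        return ""
    return ""


def _expected_roots(path: Path) -> set[str]:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".mzml"):
        return {"mzML", "indexedmzML"}
    if name.endswith(".mzxml"):
        return {"mzXML"}
    return {"mzML", "indexedmzML", "mzXML"}


def verify_integrity(path) -> bool:
    """Whether the file is well-formed XML with the root its extension implies.

    Never raises: a missing, truncated, or non-XML file is simply False.
    Truncation after the root element is also caught (full parse).
    """
    path = Path(path)
    if not path.is_file():
        return False
    root = _root_tag(path)
    if root not in _expected_roots(path):
        return False
    try:  # a valid prefix of a truncated file still yields a root: full parse
        with _open_maybe_gzip(path) as handle:
            for _ in etree.iterparse(handle, events=("end",)):
                pass
    except (etree.XMLSyntaxError, OSError, ValueError):
        return False
    return True


#: mzML controlled-vocabulary accessions for scan metadata.
_CV_MS_LEVEL = "MS:1000511"
_CV_POSITIVE = "MS:1000130"
_CV_NEGATIVE = "MS:1000129"


def _summarize_mzml(path: Path, summary: ScanSummary) -> None:
    """Streaming scan-header scan of an mzML document.

    Only ``<spectrum>`` elements are materialized and each is freed after
    its cvParams (MS level, polarity — wherever nested, e.g. under
    scanList/scan) are read; peak arrays are never decoded.
    """
    with _open_maybe_gzip(path) as handle:
        for _event, element in etree.iterparse(handle, events=("end",)):
            if etree.QName(element.tag).localname != "spectrum":
                continue
            level, polarity = 1, Polarity.UNKNOWN
            for cv in element.iter():
                if etree.QName(cv.tag).localname != "cvParam":
                    continue
                accession = cv.get("accession", "")
                if accession == _CV_MS_LEVEL:
                    level = int(cv.get("value", "1"))
                elif accession == _CV_POSITIVE:
                    polarity = Polarity.POSITIVE
                elif accession == _CV_NEGATIVE:
                    polarity = Polarity.NEGATIVE
            summary.add(level, polarity)
            element.clear()


def _summarize_mzxml(path: Path, summary: ScanSummary) -> None:
    with _open_maybe_gzip(path) as handle:
        with _mzxml.read(handle, decode_binary=False) as spectra:
            for scan in spectra:
                summary.add(int(scan.get("msLevel", 1)), _polarity_from_mzxml(scan))


def _polarity_from_mzxml(scan: dict) -> Polarity:
    flag = scan.get("polarity")
    if flag == "+":
        return Polarity.POSITIVE
    if flag == "-":
        return Polarity.NEGATIVE
    return Polarity.UNKNOWN


def summarize_scans(path, run_path: str | None = None) -> ScanSummary:
    """Stream a file's spectra and tally scans by MS level and polarity.

    The dialect is detected from the root element, not the extension.
    Spectra lacking polarity metadata count under ``unknown``; a file with
    zero spectra is valid (total 0). A file that is not readable
    mzML/mzXML raises :class:`IntegrityError` — distinct from "valid but
    empty".
    """
    path = Path(path)
    summary = ScanSummary(run_path=run_path or path.name)
    root = _root_tag(path)
    if root in ("mzML", "indexedmzML"):
        dialect = _summarize_mzml
    elif root == "mzXML":
        dialect = _summarize_mzxml
    else:
        raise IntegrityError(f"{path}: not a readable mzML/mzXML document")
    try:
        dialect(path, summary)
    except etree.XMLSyntaxError as exc:
        raise IntegrityError(f"{path}: malformed XML ({exc})") from exc
    except Exception as exc:  # pyteomics wraps parse errors variably
        raise IntegrityError(f"{path}: unreadable spectra ({exc})") from exc
    return summary
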