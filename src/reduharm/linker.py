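"""File ↔ sample record linkage and polarity-based analysis disambiguation.

Repository submitters describe their raw files inconsistently: full paths,
bare file names, names without extensions, several names packed into one
cell, or loose fragments. The linker recovers file→sample links through a
strict cascade of matching tiers, accepting a link only when it is
unambiguous:

1. ``full_path``        — descriptor equals the deposited file path
2. ``base_name``        — descriptors and paths compared by base file name
3. ``base_name_no_ext`` — base names compared after stripping one extension
4. ``separator_split``  — descriptors split on ``,``/``;``/``|`` and the
   parts re-run through tiers 1–3
5. ``substring``        — descriptor contained in the file's base name (or
   vice versa), minimum pattern length 4, unique across samples *and* files

The first tier that yields any match for a file fixes that file's link; a
file matching descriptors of two or more samples at that tier is ambiguous
and excluded. A study where no file links at all is discarded.

When one study deposited several analyses (several mwTab documents), the
per-analysis metadata of a file is only kept if exactly one analysis'
declared ion mode matches the polarity observed in the file's scan
headers; otherwise the analysis-level metadata is dropped (sample-level
metadata may survive).

All comparisons are case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .msdata import ScanSummary
from .mwtab_ingest import MwTabDocument
from .polarity import Polarity

DEFAULT_SEPARATORS = (",", ";", "|")
_MIN_SUBSTRING_LEN = 4


class Tier(Enum):
    FULL_PATH = "full_path"
    BASE_NAME = "base_name"
    BASE_NAME_NO_EXT = "base_name_no_ext"
    SEPARATOR_SPLIT = "separator_split"
    SUBSTRING = "substring"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AssociationResult:
    run_path: str
    sample_id: str
    tier: Tier
    ambiguous: bool = False


@dataclass
class StudyLinkage:
    accepted: list[AssociationResult] = field(default_factory=list)
    ambiguous: list[AssociationResult] = field(default_factory=list)
    unlinked_files: list[str] = field(default_factory=list)

    @property
    def discarded_study(self) -> bool:
        """A study with no accepted link contributes nothing downstream."""
        return not self.accepted


def _norm(text: str) -> str:
    return text.strip().lower()


def _base(path: str) -> str:
    return path.replace("\\", "/").rsplit("/", 1)[-1]


def _strip_ext(name: str) -> str:
    return name.rsplit(".", 1)[0] if "." in name else name


def _match_full(descriptor: str, file_path: str) -> bool:
    return _norm(descriptor) == _norm(file_path)


def _match_base(descriptor: str, file_path: str) -> bool:
    return _norm(_base(descriptor)) == _norm(_base(file_path))


def _match_base_no_ext(descriptor: str, file_path: str) -> bool:
    return _norm(_strip_ext(_base(descriptor))) == _norm(_strip_ext(_base(file_path)))


def _split_descriptor(descriptor: str, separators: tuple[str, ...]) -> list[str]:
    pattern = "|".join(re.escape(s) for s in separators)
    return [part.strip() for part in re.split(pattern, descriptor) if part.strip()]


def _matching_samples(
    file_path: str,
    descriptors: dict[str, list[str]],
    comparator,
    split: tuple[str, ...] | None,
) -> set[str]:
    """Samples with ≥1 descriptor (or split part) matching the file."""
    hits = set()
    for sample_id, values in descriptors.items():
        for value in values:
            parts = _split_descriptor(value, split) if split else [value]
            if any(comparator(part, file_path) for part in parts):
                hits.add(sample_id)
                break
    return hits


def _substring_pairs(
    files: list[str], descriptors: dict[str, list[str]]
) -> dict[str, set[str]]:
    """file → matching samples under the substring rule (length-guarded,
    bidirectional containment on extension-stripped base names)."""
    out: dict[str, set[str]] = {f: set() for f in files}
    for file_path in files:
        stem = _norm(_strip_ext(_base(file_path)))
        for sample_id, values in descriptors.items():
            for value in values:
                desc = _norm(_strip_ext(_base(value)))
                shorter = min(desc, stem, key=len)
                if len(shorter) < _MIN_SUBSTRING_LEN:
                    continue
                if desc in stem or stem in desc:
                    out[file_path].add(sample_id)
                    break
    return out


def associate_files(
    files: list[str],
    descriptors: dict[str, list[str]],
    separators: tuple[str, ...] = DEFAULT_SEPARATORS,
) -> StudyLinkage:
    """Run the matching cascade over one study's files and descriptors.

    Tiers are attempted strictly in order; the first tier that yields any
    match for a file fixes that file's fate — a unique sample accepts the
    link, two or more samples make the file ambiguous and excluded. At the
    substring tier a link must additionally be unique across files (the
    same descriptor fragment matching two unlinked files rejects both).
    """
    if not files:
        raise ValueError("files must be non-empty")

    linkage = StudyLinkage()
    remaining = list(files)

    exact_tiers = [
        (Tier.FULL_PATH, _match_full, None),
        (Tier.BASE_NAME, _match_base, None),
        (Tier.BASE_NAME_NO_EXT, _match_base_no_ext, None),
        (Tier.SEPARATOR_SPLIT, _match_full, separators),
        (Tier.SEPARATOR_SPLIT, _match_base, separators),
        (Tier.SEPARATOR_SPLIT, _match_base_no_ext, separators),
    ]
    for tier, comparator, split in exact_tiers:
        still = []
        for file_path in remaining:
            hits = _matching_samples(file_path, descriptors, comparator, split)
            if len(hits) == 1:
                linkage.accepted.append(AssociationResult(file_path, hits.pop(), tier))
            elif len(hits) > 1:
                linkage.ambiguous.append(
                    AssociationResult(file_path, "", tier, ambiguous=True))
            else:
                still.append(file_path)
        remaining = still

    # Substring tier: uniqueness across samples and across files.
    pairs = _substring_pairs(remaining, descriptors)
    sample_to_files: dict[str, list[str]] = {}
    for file_path, samples in pairs.items():
        for sample_id in samples:
            sample_to_files.setdefault(sample_id, []).append(file_path)
    for file_path in remaining:
        samples = pairs[file_path]
        if not samples:
            linkage.unlinked_files.append(file_path)
            continue
        if len(samples) > 1:
            linkage.ambiguous.append(
                AssociationResult(file_path, "", Tier.SUBSTRING, ambiguous=True))
            continue
        sample_id = next(iter(samples))
        if len(sample_to_files[sample_id]) > 1:
            linkage.ambiguous.append(
                AssociationResult(file_path, "", Tier.SUBSTRING, ambiguous=True))
            continue
        linkage.accepted.append(AssociationResult(file_path, sample_id, Tier.SUBSTRING))
    return linkage


DROPPED = None  # sentinel outcome of polarity disambiguation


def file_polarity(summary: ScanSummary) -> Polarity:
    """Collapse a scan summary to one polarity, or UNKNOWN when mixed/absent."""
    observed = {pol for (_level, pol), count in summary.counts.items()
                if count > 0 and pol != Polarity.UNKNOWN}
    if len(observed) == 1:
        return observed.pop()
    return Polarity.UNKNOWN


def disambiguate_by_polarity(
    analyses: list[MwTabDocument],
    files: list[tuple[str, ScanSummary]],
) -> dict[str, str | None]:
    """Assign each raw file to the unique analysis matching its polarity.

    Only meaningful when a study deposited ≥2 analyses (a single analysis
    trivially owns every file). A file whose scans are uniformly one
    polarity maps to the sole analysis declaring that polarity; if no
    analysis or several remain compatible — including mixed-polarity files
    and analyses with unspecified ion mode — the file's analysis-level
    metadata is dropped (mapped to ``DROPPED``/None).
    """
    if len(analyses) == 1:
        only = analyses[0].analysis_id
        return {run_path: only for run_path, _summary in files}

    by_polarity: dict[Polarity, list[str]] = {}
    for doc in analyses:
        by_polarity.setdefault(doc.polarity, []).append(doc.analysis_id)

    assignment: dict[str, str | None] = {}
    for run_path, summary in files:
        observed = file_polarity(summary)
        if observed == Polarity.UNKNOWN:
            assignment[run_path] = DROPPED
            continue
        compatible = by_polarity.get(observed, [])
        assignment[run_path] = compatible[0] if len(compatible) == 1 else DROPPED
    return assignment


def write_linkage_report(linkage: StudyLinkage, path) -> None:
    """TSV report: run_path, sample_id, tier, status."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["run_path", "sample_id", "tier", "status"])
        for result in linkage.accepted:
            writer.writerow([result.run_path, result.sample_id, result.tier.value, "accepted"])
        for result in linkage.ambiguous:
            writer.writerow([result.run_path, "", result.tier.value, "ambiguous"])
        for run_path in linkage.unlinked_files:
            writer.writerow([run_path, "", "", "unlinked"])
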