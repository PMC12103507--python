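"""MS Run Identifiers (MRIs): parse, format, classify, validate.

An MRI names one raw mass-spectrometry run inside a public repository:
``mzspec:<dataset accession>:<relative file path>``. It is the
dataset-and-file-path subset of the Universal Spectrum Identifier (USI)
standard — a USI without the scan-level suffix. Scan-level USIs
(``...:scan:17``) are accepted and truncated to their MRI.

The accession decides which repository hosts the run; the registry of
accession patterns is configurable so new repositories need no code change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

SCHEME_PREFIX = "mzspec"

#: Raw-data file formats indexed by the harmonizer. ``.d`` is a
#: directory-style vendor format but is matched as a terminal suffix like
#: the rest; matching is case-insensitive.
SUPPORTED_EXTENSIONS = frozenset({"mzml", "mzxml", "raw", "wiff", "cdf", "d"})
OPEN_EXTENSIONS = frozenset({"mzml", "mzxml"})
VENDOR_EXTENSIONS = frozenset({"raw", "wiff", "cdf", "d"})

#: USI index types whose suffix we truncate when reducing a USI to an MRI.
_USI_INDEX_TYPES = frozenset({"scan", "index", "nativeId"})


class MriError(ValueError):
    """Base class for MRI parsing problems."""


class MriPrefixError(MriError):
    """The identifier does not start with the ``mzspec`` scheme prefix."""


class UnknownRepositoryError(MriError):
    """The accession matches no registered repository pattern."""


class MriPathError(MriError):
    """The run path is empty, absolute, traversing, or contains bare colons."""


@dataclass(frozen=True)
class RepositoryTag:
    """A supported repository and its anchored accession pattern."""

    name: str
    accession_pattern: str

    def matches(self, accession: str) -> bool:
        return re.fullmatch(self.accession_pattern, accession) is not None


GNPS_MASSIVE = RepositoryTag("GNPS/MassIVE", r"MSV\d{9}")
MTBLS = RepositoryTag("MTBLS", r"MTBLS\d+")
NMDR = RepositoryTag("NMDR", r"ST\d{6}")

DEFAULT_REPOSITORIES: tuple[RepositoryTag, ...] = (GNPS_MASSIVE, MTBLS, NMDR)


@dataclass(frozen=True)
class MsRunIdentifier:
    """One raw file in one public dataset: the universal key of the table."""

    dataset_accession: str
    run_path: str
    repository: RepositoryTag = field(compare=False)

    def __str__(self) -> str:
        return format_mri(self)

    @property
    def extension(self) -> str:
        """Terminal file extension, lower-cased, without the dot."""
        name = self.run_path.rsplit("/", 1)[-1]
        if "." not in name:
            return ""
        return name.rsplit(".", 1)[-1].lower()


def classify_repository(
    accession: str, registry: tuple[RepositoryTag, ...] = DEFAULT_REPOSITORIES
) -> RepositoryTag:
    """Return the unique repository whose accession pattern matches.

    Patterns are mutually exclusive by construction; a multiple match is a
    registry misconfiguration and raises ``ValueError``.
    """
    if not accession:
        raise UnknownRepositoryError("empty accession")
    hits = [tag for tag in registry if tag.matches(accession)]
    if not hits:
        raise UnknownRepositoryError(f"accession {accession!r} matches no supported repository")
    if len(hits) > 1:  # registry invariant violated
        raise ValueError(f"accession {accession!r} matched multiple repositories: {hits}")
    return hits[0]


def _validate_run_path(run_path: str) -> None:
    if not run_path:
        raise MriPathError("run path is empty")
    if run_path.startswith("/"):
        raise MriPathError(f"run path {run_path!r} must be relative (no leading slash)")
    if any(seg == ".." for seg in run_path.split("/")):
        raise MriPathError(f"run path {run_path!r} contains a path-traversal segment")


def make_mri(
    dataset_accession: str,
    run_path: str,
    registry: tuple[RepositoryTag, ...] = DEFAULT_REPOSITORIES,
) -> MsRunIdentifier:
    """Build a validated MRI from its components."""
    repo = classify_repository(dataset_accession, registry)
    _validate_run_path(run_path)
    return MsRunIdentifier(dataset_accession, run_path, repo)


def parse_mri(
    text: str, registry: tuple[RepositoryTag, ...] = DEFAULT_REPOSITORIES
) -> MsRunIdentifier:
    """Parse an MRI string of the form ``mzspec:<accession>:<path>``.

    The string is split at its first two colons, so run paths may contain
    colons only percent-encoded; a bare colon in the path is rejected —
    unless the trailing segments form a USI scan suffix
    (``:scan:<n>`` etc.), which is truncated away.
    """
    parts = text.split(":")
    if not parts or parts[0] != SCHEME_PREFIX:
        raise MriPrefixError(
            f"identifier {text!r} does not start with the {SCHEME_PREFIX!r} scheme prefix"
        )
    if len(parts) < 3:
        raise MriPathError(f"identifier {text!r} lacks an accession or run path")
    if len(parts) > 3:
        # A full USI carries mzspec:collection:run:indexType:indexNumber[...]
        if len(parts) >= 5 and parts[3] in _USI_INDEX_TYPES:
            parts = parts[:3]
        else:
            raise MriPathError(f"run path in {text!r} contains a bare colon")
    accession, run_path = parts[1], parts[2]
    return make_mri(accession, run_path, registry)


def format_mri(mri: MsRunIdentifier) -> str:
    """Inverse of :func:`parse_mri` on the valid-MRI space."""
    return f"{SCHEME_PREFIX}:{mri.dataset_accession}:{mri.run_path}"


def has_supported_extension(run_path: str) -> bool:
    """True iff the path's terminal extension is an indexed raw-data format."""
    name = run_path.rsplit("/", 1)[-1]
    if "." not in name:
        return False
    return name.rsplit(".", 1)[-1].lower() in SUPPORTED_EXTENSIONS


def read_mri_list(path) -> list[MsRunIdentifier]:
    """Read a one-MRI-per-line text file (blank lines and ``#`` comments skipped)."""
    mris = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mris.append(parse_mri(line))
    return mris
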