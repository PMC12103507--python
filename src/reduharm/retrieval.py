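"""MRI-driven raw-data retrieval: cache, download, per-file reporting.

Retrieval is a three-step workflow per requested MRI:

1. *cache probe* — a previously downloaded copy that passes integrity
   verification (well-formed XML for mzML/mzXML; non-empty otherwise) is
   served immediately;
2. *download* — on a miss or a failed check the file is fetched from the
   repository backend, written atomically (temp file + rename, so an
   interrupted download is never visible as a cache entry) and re-verified;
3. *report* — every MRI gets an explicit outcome (cache hit, downloaded,
   healed corruption, or an error with its reason); partial failures never
   abort the batch.

Backends are pluggable: tests and offline use run against the filesystem
:class:`MockBackend`; thin HTTP adapters for the public repositories are
provided but deliberately outside the test surface.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Protocol

from .identifiers import OPEN_EXTENSIONS, VENDOR_EXTENSIONS, MsRunIdentifier, format_mri
from .msdata import verify_integrity


class NotFound(Exception):
    """The backend does not serve this MRI."""


class RepositoryBackend(Protocol):
    def resolve(self, mri: MsRunIdentifier) -> bytes:
        """Return the file's bytes or raise :class:`NotFound`.

        Must be repeatable: identical MRI, identical bytes.
        """
        ...  # pragma: no cover


class MockBackend:
    """Filesystem-backed repository: files live at ``root/accession/path``."""

    def __init__(self, root) -> None:
        self.root = Path(root)

    def resolve(self, mri: MsRunIdentifier) -> bytes:
        path = self.root / mri.dataset_accession / mri.run_path
        if not path.is_file():
            raise NotFound(format_mri(mri))
        return path.read_bytes()


class HttpBackend:
    """Minimal HTTP adapter: substitutes accession/path into a URL template.

    Endpoint conventions drift; the template is config-overridable. Not
    exercised by the offline test suite.
    """

    def __init__(self, url_template: str, timeout: float = 60.0) -> None:
        self.url_template = url_template
        self.timeout = timeout

    def resolve(self, mri: MsRunIdentifier) -> bytes:  # pragma: no cover - network
        import urllib.error
        import urllib.request

        url = self.url_template.format(accession=mri.dataset_accession, path=mri.run_path)
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as response:
                return response.read()
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise NotFound(format_mri(mri)) from exc
            raise


#: Default URL templates per repository name (override via config JSON).
DEFAULT_BACKEND_CONFIG = {
    "GNPS/MassIVE": "https://datasetcache.gnps2.org/datasette/database/filename/{accession}/{path}",
    "MTBLS": "https://www.ebi.ac.uk/metabolights/ws/studies/{accession}/download/public?file={path}",
    "NMDR": "https://www.metabolomicsworkbench.org/data/file/{accession}/{path}",
}


def backends_from_config(config: dict[str, str]) -> dict[str, RepositoryBackend]:
    return {name: HttpBackend(url) for name, url in config.items()}


class Outcome(Enum):
    CACHE_HIT = "cache_hit"
    DOWNLOADED = "downloaded"
    HEALED = "integrity_failed_then_redownloaded"
    ERROR = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MriOutcome:
    mri: str
    outcome: Outcome
    reason: str = ""


@dataclass
class RetrievalReport:
    per_mri: dict[str, MriOutcome] = field(default_factory=dict)

    @property
    def cache_hits(self) -> int:
        return sum(1 for o in self.per_mri.values() if o.outcome == Outcome.CACHE_HIT)

    @property
    def downloads(self) -> int:
        return sum(1 for o in self.per_mri.values()
                   if o.outcome in (Outcome.DOWNLOADED, Outcome.HEALED))

    @property
    def errors(self) -> int:
        return sum(1 for o in self.per_mri.values() if o.outcome == Outcome.ERROR)

    @property
    def successes(self) -> int:
        return len(self.per_mri) - self.errors

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            with open(tsv_path, "w", encoding="utf-8", newline="") as handle:
                writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
                writer.writerow(["mri", "outcome", "reason"])
                for outcome in self.per_mri.values():
                    writer.writerow([outcome.mri, outcome.outcome.value, outcome.reason])
        if json_path is not None:
            payload = {
                "totals": {"requested": len(self.per_mri), "success": self.successes,
                           "cache_hits": self.cache_hits, "downloads": self.downloads,
                           "errors": self.errors},
                "per_mri": {o.mri: {"outcome": o.outcome.value, "reason": o.reason}
                            for o in self.per_mri.values()},
            }
            Path(json_path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def cache_path(cache_dir, mri: MsRunIdentifier) -> Path:
    """Cache key is ``accession/run_path`` — the MRI's own coordinates."""
    return Path(cache_dir) / mri.dataset_accession / mri.run_path


def _is_intact(path: Path, mri: MsRunIdentifier) -> bool:
    if mri.extension in OPEN_EXTENSIONS:
        return verify_integrity(path)
    # Integrity is only defined as XML validity for the open formats; for
    # vendor/cdf payloads a weaker non-empty check is all that is possible.
    return path.is_file() and path.stat().st_size > 0


def _atomic_write(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".partial-")
    try:
        with os.fdopen(fd, "wb") as handle:
            handle.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def fetch(
    mris: list[MsRunIdentifier],
    cache_dir,
    backends: dict[str, RepositoryBackend],
) -> RetrievalReport:
    """Retrieve a batch of MRIs through the cache into ``cache_dir``.

    Conservation holds by construction: every requested MRI appears exactly
    once in the report and cache hits + downloads + errors == requests.
    """
    report = RetrievalReport()
    for mri in mris:
        key = format_mri(mri)
        backend = backends.get(mri.repository.name)
        if backend is None:
            report.per_mri[key] = MriOutcome(key, Outcome.ERROR,
                                             f"no backend registered for {mri.repository.name}")
            continue
        target = cache_path(cache_dir, mri)
        had_copy = target.exists()
        if had_copy and _is_intact(target, mri):
            report.per_mri[key] = MriOutcome(key, Outcome.CACHE_HIT)
            continue
        try:
            data = backend.resolve(mri)
        except NotFound:
            report.per_mri[key] = MriOutcome(key, Outcome.ERROR, "not found in repository")
            continue
        except OSError as exc:
            report.per_mri[key] = MriOutcome(key, Outcome.ERROR, f"backend I/O failure: {exc}")
            continue
        _atomic_write(target, data)
        if not _is_intact(target, mri):
            report.per_mri[key] = MriOutcome(key, Outcome.ERROR,
                                             "downloaded copy failed integrity verification")
            continue
        outcome = Outcome.HEALED if had_copy else Outcome.DOWNLOADED
        report.per_mri[key] = MriOutcome(key, outcome)
    return report


@dataclass(frozen=True)
class ConversionTicket:
    """Receipt for a requested vendor→mzML conversion (delegated service)."""

    mri: str
    issued_at: _dt.datetime
    expires_at: _dt.datetime


class Converter(Protocol):
    def submit(self, mri: MsRunIdentifier) -> None: ...  # pragma: no cover


def request_conversion(
    mri: MsRunIdentifier,
    converter: Converter | None = None,
    now: _dt.datetime | None = None,
) -> ConversionTicket:
    """Request conversion of a vendor-format file; converted copies stay
    available for 30 days. The conversion itself is delegated to the
    injected converter interface — only the ticket is modelled here."""
    if mri.extension not in VENDOR_EXTENSIONS:
        raise ValueError(f"{format_mri(mri)}: conversion applies to vendor formats only, "
                         f"not .{mri.extension or '?'}")
    if converter is not None:
        converter.submit(mri)
    issued = now or _dt.datetime.now(_dt.timezone.utc)
    return ConversionTicket(format_mri(mri), issued, issued + _dt.timedelta(days=30))
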