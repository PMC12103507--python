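"""Cache-aware retrieval of raw files by MRI, with per-file reporting.

Runs the three-step workflow (cache probe with integrity check, backend
download, transparent report) against a local mock repository, then
corrupts a cached file to show the self-healing re-download.
"""

import tempfile
from pathlib import Path

from reduharm import MockBackend, fetch, make_mri
from reduharm.fixtures import generate_mzml, truncate_file
from reduharm.polarity import Polarity
from reduharm.retrieval import cache_path

tmp = Path(tempfile.mkdtemp())
repo = tmp / "repo"
mris = []
for i in range(3):
    mri = make_mri("ST000001", f"raw/f{i}.mzML")
    generate_mzml([(1, Polarity.POSITIVE)] * (i + 1), repo / "ST000001" / mri.run_path)
    mris.append(mri)
mris.append(make_mri("ST000001", "raw/missing.mzML"))  # not in the repository

backends = {"NMDR": MockBackend(repo)}
cache = tmp / "cache"

for label in ("cold cache", "warm cache"):
    report = fetch(mris, cache, backends)
    print(f"{label}: hits={report.cache_hits} downloads={report.downloads} "
          f"errors={report.errors}  (conservation: "
          f"{report.cache_hits + report.downloads + report.errors} == {len(mris)})")

# Corrupt one cached copy: the next fetch detects the broken XML and heals it.
truncate_file(cache_path(cache, mris[0]), 0.4)
report = fetch(mris, cache, backends)
print("after corruption:", report.per_mri[str(mris[0])].outcome.value)

# Every requested MRI appears exactly once in the report; the missing file
# is a per-file error, never an aborted batch.
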