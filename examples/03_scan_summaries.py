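"""Scan-level summaries: MS levels and polarities straight from raw files.

Writes a small mzML and mzXML file with known scans, then reads back
per-file tallies — the same summaries that drive the MS/MS availability
statistics and the polarity-based analysis disambiguation.
"""

import tempfile
from pathlib import Path

from reduharm import has_msms, summarize_scans, verify_integrity
from reduharm.fixtures import generate_mzml, generate_mzxml, truncate_file
from reduharm.polarity import Polarity

tmp = Path(tempfile.mkdtemp())

mzml = generate_mzml([(1, Polarity.POSITIVE)] * 3 + [(2, Polarity.POSITIVE)] * 2,
                     tmp / "pos_ddA.mzML")
mzxml = generate_mzxml([(1, Polarity.NEGATIVE)] * 4, tmp / "neg_ms1.mzXML")

for path in (mzml, mzxml):
    summary = summarize_scans(path)
    print(f"{path.name}: total={summary.total_scans} msms={has_msms(summary)}")
    for (level, polarity), count in sorted(summary.counts.items(),
                                           key=lambda kv: (kv[0][0], kv[0][1].value)):
        print(f"  MS{level} {polarity.value}: {count} scans")

# Integrity: the cache treats an mzML as valid only if it is well-formed XML.
truncate_file(mzml, 0.5)
print(f"after truncation, {mzml.name} intact: {verify_integrity(mzml)}")

# The first file is a typical data-dependent positive-mode acquisition
# (MS1 survey + MS/MS); the second is negative-mode MS1-only, as common in
# clinical untargeted profiling.
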