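"""The file↔sample matching cascade on deliberately messy descriptors.

Submitters describe raw files inconsistently; the cascade tries exact
tiers first (full path, base name, stripped extension), then splits
multi-file cells, then falls back to guarded substring matching — and
accepts a link only when it is unambiguous.
"""

from reduharm import associate_files

files = [
    "raw/pos/plasma_A1.mzML",   # referenced by full path
    "plasma_B2.mzML",           # referenced by base name with wrong extension
    "batch1_C3.mzML",           # two files deposited in one cell
    "batch1_C4.mzML",
    "longrun_D5.mzML",          # referenced only by a name fragment
    "mystery.mzML",             # never referenced → unlinked
    "shared.mzML",              # claimed by two samples → ambiguous
]
descriptors = {
    "Sample_A": ["raw/pos/plasma_A1.mzML"],
    "Sample_B": ["plasma_B2.raw"],
    "Sample_C": ["batch1_C3.raw; batch1_C4.raw"],
    "Sample_D": ["longrun_D"],
    "Sample_E": ["shared.mzML"],
    "Sample_F": ["shared.mzML"],
}

linkage = associate_files(files, descriptors)
for link in linkage.accepted:
    print(f"accepted  {link.run_path:24s} → {link.sample_id:9s} via {link.tier.value}")
for link in linkage.ambiguous:
    print(f"ambiguous {link.run_path:24s} (excluded: claimed by several samples)")
for run_path in linkage.unlinked_files:
    print(f"unlinked  {run_path}")
print(f"study discarded: {linkage.discarded_study}")

# Five files link, each at a different tier; the shared descriptor is
# rejected rather than guessed, and a study linking nothing would be
# discarded outright.
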