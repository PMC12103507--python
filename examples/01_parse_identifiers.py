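"""MS Run Identifiers: the universal key for raw files across repositories.

An MRI packs a dataset accession and a file path into one string,
``mzspec:<accession>:<path>``, so a single identifier can name any raw
file in MetaboLights, Metabolomics Workbench, or GNPS/MassIVE.
"""

from reduharm import classify_repository, format_mri, has_supported_extension, parse_mri

for text in [
    "mzspec:MSV000085852:ccms_peak/a/sample1.mzML",
    "mzspec:MTBLS1234:FILES/study_run_07.mzXML",
    "mzspec:ST000422:raw/plasma_pos_012.raw",
    "mzspec:ST000001:raw/x.mzML:scan:17",  # scan-level USI → truncated to its MRI
]:
    mri = parse_mri(text)
    print(f"{format_mri(mri):55s} repo={mri.repository.name:12s} "
          f"supported_format={has_supported_extension(mri.run_path)}")

# The accession alone decides the hosting repository:
print("ST001234 →", classify_repository("ST001234").name)

# Each line shows the canonical identifier, which repository serves it, and
# whether the file's extension is one of the six indexed raw-data formats.
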