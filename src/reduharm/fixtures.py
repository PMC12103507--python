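"""Synthetic mini-repositories with planted ground truth.

Every pipeline stage is exercised against data this module generates:
mwTab analyses whose sample descriptors force each linkage tier, ISA-Tab
studies with vendor/open duplicate files and submitter-named factor
columns, ReDU-native tables, and schema-minimal mzML/mzXML files with
chosen MS levels and polarities. Generation is a pure function of a seeded
spec — identical seed, byte-identical output tree — and each generated
study returns a manifest stating exactly what the harmonizer must recover.

Deliberately ambiguous constructs (two samples claiming one base name, two
analyses sharing a polarity) are planted on request so tests can assert
that precisely those constructs are rejected and nothing else.
"""

from __future__ import annotations

import base64
import random
import struct
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .linker import Tier
from .polarity import Polarity

# ---------------------------------------------------------------------------
# Raw-file generation


def _encode_peak(mz: float = 100.0, intensity: float = 1.0) -> str:
    return base64.b64encode(struct.pack("<dd", mz, intensity)).decode("ascii")


def _encode_peak_network(mz: float = 100.0, intensity: float = 1.0) -> str:
    return base64.b64encode(struct.pack(">dd", mz, intensity)).decode("ascii")


_MZML_POLARITY_CV = {
    Polarity.POSITIVE: '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
    Polarity.NEGATIVE: '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
    Polarity.UNKNOWN: "",
}


def generate_mzml(scan_spec: list[tuple[int, Polarity]], out) -> Path:
    """Write a schema-minimal, well-formed mzML file with the given scans.

    Each entry of ``scan_spec`` is one spectrum (MS level, polarity); a
    1-point dummy peak array keeps validators content while the file stays
    tiny. An empty spec yields a valid zero-spectrum file.
    """
    out = Path(out)
    peak = _encode_peak()
    spectra = []
    for index, (level, polarity) in enumerate(scan_spec):
        if level < 1:
            raise ValueError(f"ms_level must be >= 1, got {level}")
        spectra.append(f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="1">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        {_MZML_POLARITY_CV[polarity]}
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(peak)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{peak}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(peak)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{peak}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "\n".join(spectra)
    text = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{escape(out.stem)}">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{escape(out.stem)}">
    <spectrumList count="{len(scan_spec)}">
{body}
    </spectrumList>
  </run>
</mzML>
"""
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(text, encoding="utf-8")
    return out


def generate_mzxml(scan_spec: list[tuple[int, Polarity]], out) -> Path:
    """mzXML 3.2 sibling of :func:`generate_mzml` (network byte order)."""
    out = Path(out)
    peak = _encode_peak_network()
    flag = {Polarity.POSITIVE: "+", Polarity.NEGATIVE: "-", Polarity.UNKNOWN: None}
    scans = []
    for index, (level, polarity) in enumerate(scan_spec):
        if level < 1:
            raise ValueError(f"ms_level must be >= 1, got {level}")
        polarity_attr = f' polarity="{flag[polarity]}"' if flag[polarity] else ""
        scans.append(f"""    <scan num="{index + 1}" msLevel="{level}"{polarity_attr} peaksCount="1">
      <peaks compressionType="none" compressedLen="0" precision="64" byteOrder="network" contentType="m/z-int">{peak}</peaks>
    </scan>""")
    body = "\n".join(scans)
    text = f"""<?xml version="1.0" encoding="utf-8"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
  <msRun scanCount="{len(scan_spec)}">
{body}
  </msRun>
</mzXML>
"""
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(text, encoding="utf-8")
    return out


def truncate_file(path, fraction: float = 0.5) -> Path:
    """Corrupt a file in place by keeping only the leading fraction of bytes."""
    path = Path(path)
    data = path.read_bytes()
    path.write_bytes(data[: max(1, int(len(data) * fraction))])
    return path


# ---------------------------------------------------------------------------
# Study specs and manifests

#: (repository label as deposited, harmonized term) pairs the generator
#: draws from; both sides are known so the manifest states exact outputs.
ORGANISMS = [("Homo sapiens", "9606|Homo sapiens"), ("Mus musculus", "10090|Mus musculus")]
BODY_PARTS = [("Urine", "urine"), ("Plasma", "blood plasma"), ("Liver", "liver")]
INSTRUMENTS = [("Q Exactive", "Q Exactive"), ("timsTOF Pro", "timsTOF Pro")]


@dataclass
class StudySpec:
    """Recipe for one synthetic study; generation is pure in (spec, seed)."""

    repository: str  # "NMDR" | "MTBLS" | "GNPS/MassIVE"
    accession: str
    seed: int = 0
    # NMDR linkage plan: one file per entry, each planted at the given tier.
    tier_plan: tuple[Tier, ...] = (Tier.FULL_PATH,)
    n_unlinked: int = 0
    ambiguous_basename: int = 0  # files claimed by two samples at base_name
    analyses: tuple[Polarity, ...] = (Polarity.POSITIVE,)
    # MTBLS plan
    n_samples: int = 3
    vendor_duplicates: int = 0  # samples deposited in both .raw and .mzML
    # shared metadata choices (indices into the tables above)
    organism: int = 0
    body_part: int = 0
    instrument: int = 0
    year: int = 2021


@dataclass
class StudyManifest:
    """What the harmonizer must recover from a generated study."""

    accession: str
    repository: str
    expected_links: dict[str, tuple[str, str]] = field(default_factory=dict)  # run_path → (tier, sample)
    expected_ambiguous: set[str] = field(default_factory=set)
    expected_unlinked: set[str] = field(default_factory=set)
    analysis_assignment: dict[str, str | None] = field(default_factory=dict)
    expected_records: dict[str, dict[str, str]] = field(default_factory=dict)  # MRI → fields
    scan_specs: dict[str, list[tuple[int, Polarity]]] = field(default_factory=dict)
    discarded: bool = False


def _tokens(rng: random.Random, n: int, length: int = 8) -> list[str]:
    """Distinct same-length lowercase tokens, no token a substring of
    another (same length ⇒ substring only if equal) and no planted
    fragment colliding across tokens."""
    alphabet = "abcdefghijklmnopqrstuvwxyz0123456789"
    while True:
        out = ["".join(rng.choice(alphabet) for _ in range(length)) for _ in range(n)]
        fragments = [t[1:-1] for t in out]
        ok = len(set(out)) == n and all(
            sum(1 for t in out if frag in t) == 1 for frag in fragments
        ) and len(set(fragments)) == n
        if ok:
            return out


def _scan_spec_for(polarity: Polarity, rng: random.Random) -> list[tuple[int, Polarity]]:
    n_ms1 = rng.randint(1, 3)
    n_ms2 = rng.randint(0, 2)
    return [(1, polarity)] * n_ms1 + [(2, polarity)] * n_ms2


# -- NMDR dialect -----------------------------------------------------------

_MWTAB_TEMPLATE_SECTIONS = (
    ("PROJECT", (("PROJECT_TITLE", "Synthetic harmonization fixture"),
                 ("PROJECT_DATE", "{year}-06-01"))),
    ("SUBJECT", (("SUBJECT_TYPE", "Human"),
                 ("SUBJECT_SPECIES", "{organism}"),
                 ("GENDER", "Female"))),
    ("COLLECTION", (("SAMPLE_TYPE", "{body_part}"),)),
    ("CHROMATOGRAPHY", (("CHROMATOGRAPHY_TYPE", "Reversed phase"),)),
    ("MS", (("INSTRUMENT_NAME", "{instrument}"),
            ("MS_TYPE", "ESI"),
            ("ION_MODE", "{ion_mode}"))),
)


def _descriptor_for_tier(tier: Tier, run_path: str, decoy: str) -> str:
    base = run_path.rsplit("/", 1)[-1]
    stem = base.rsplit(".", 1)[0]
    if tier == Tier.FULL_PATH:
        return run_path
    if tier == Tier.BASE_NAME:
        return base
    if tier == Tier.BASE_NAME_NO_EXT:
        return stem + ".raw"  # different extension: only the stem matches
    if tier == Tier.SEPARATOR_SPLIT:
        return f"{base}; {decoy}.raw"
    if tier == Tier.SUBSTRING:
        return stem[1:-1]  # proper fragment, unique by token construction
    raise ValueError(tier)


def _generate_nmdr(spec: StudySpec, out: Path) -> StudyManifest:
    from .mwtab_ingest import MwTabDocument, SampleFactorRow, serialize_mwtab

    rng = random.Random(spec.seed)
    manifest = StudyManifest(spec.accession, spec.repository)
    organism_raw, organism_term = ORGANISMS[spec.organism]
    body_raw, body_term = BODY_PARTS[spec.body_part]
    instrument_raw, instrument_term = INSTRUMENTS[spec.instrument]

    n_linked = len(spec.tier_plan)
    n_files = n_linked + spec.n_unlinked + spec.ambiguous_basename
    tokens = _tokens(rng, n_files + 1)
    decoy = "zz" + tokens[-1]

    analysis_ids = [f"AN{i + 1:06d}" for i in range(len(spec.analyses))]
    polarity_counts: dict[Polarity, int] = {}
    for pol in spec.analyses:
        polarity_counts[pol] = polarity_counts.get(pol, 0) + 1

    rows: list[SampleFactorRow] = []
    file_polarities: dict[str, Polarity] = {}
    distinct_polarities = list(dict.fromkeys(spec.analyses))

    def assign_polarity(i: int) -> Polarity:
        return distinct_polarities[i % len(distinct_polarities)]

    for i, tier in enumerate(spec.tier_plan):
        token = tokens[i]
        sample_id = f"{spec.accession}_S{i + 1:02d}"
        run_path = f"raw/{token}.mzML"
        descriptor = _descriptor_for_tier(tier, run_path, decoy)
        rows.append(SampleFactorRow(
            sample_id=sample_id,
            factors={"Treatment": "A"},
            additional_data={"RAW_FILE_NAME": descriptor},
        ))
        manifest.expected_links[run_path] = (tier.value, sample_id)
        file_polarities[run_path] = assign_polarity(i)

    for j in range(spec.ambiguous_basename):
        token = tokens[n_linked + j]
        run_path = f"raw/{token}.mzML"
        base = token + ".mzML"
        for flavor in ("a", "b"):
            rows.append(SampleFactorRow(
                sample_id=f"{spec.accession}_AMB{j + 1}{flavor}",
                additional_data={"RAW_FILE_NAME": base},
            ))
        manifest.expected_ambiguous.add(run_path)
        file_polarities[run_path] = assign_polarity(j)

    for k in range(spec.n_unlinked):
        token = tokens[n_linked + spec.ambiguous_basename + k]
        run_path = f"raw/{token}.mzML"
        manifest.expected_unlinked.add(run_path)
        file_polarities[run_path] = assign_polarity(k)

    ion_labels = {Polarity.POSITIVE: "POSITIVE", Polarity.NEGATIVE: "NEGATIVE",
                  Polarity.UNSPECIFIED: ""}
    for analysis_id, polarity in zip(analysis_ids, spec.analyses):
        doc = MwTabDocument(analysis_id=analysis_id, study_id=spec.accession,
                            header_line=f"#METABOLOMICS WORKBENCH STUDY_ID:{spec.accession} ANALYSIS_ID:{analysis_id}")
        values = {"year": str(spec.year), "organism": organism_raw,
                  "body_part": body_raw, "instrument": instrument_raw,
                  "ion_mode": ion_labels[polarity]}
        for section, entries in _MWTAB_TEMPLATE_SECTIONS:
            doc.sections[section] = {k: v.format(**values) for k, v in entries}
        doc.subject_sample_factors = rows
        (out / f"{analysis_id}.mwtab").write_text(serialize_mwtab(doc), encoding="utf-8")

    for run_path, polarity in file_polarities.items():
        scan_spec = _scan_spec_for(polarity, rng)
        generate_mzml(scan_spec, out / run_path)
        manifest.scan_specs[run_path] = scan_spec

    # Expected analysis assignment and records for accepted links.
    multi = len(spec.analyses) > 1
    for run_path, (tier_value, sample_id) in manifest.expected_links.items():
        polarity = file_polarities[run_path]
        if not multi:
            assigned = analysis_ids[0]
        elif polarity_counts.get(polarity, 0) == 1:
            assigned = analysis_ids[spec.analyses.index(polarity)]
        else:
            assigned = None
        manifest.analysis_assignment[run_path] = assigned
        fields = {"NCBITaxonomy": organism_term, "UBERONBodyPartName": body_term,
                  "BiologicalSex": "female", "SampleType": "biological"}
        if assigned is not None:
            polarity_suffix = {Polarity.POSITIVE: " (positive)", Polarity.NEGATIVE: " (negative)"}
            fields.update({
                "MassSpectrometer": instrument_term,
                "ChromatographyAndPhase": "reverse phase (C18)",
                "IonizationSourceAndPolarity": "electrospray ionization" + polarity_suffix.get(polarity, ""),
                "YearOfAnalysis": str(spec.year),
            })
        mri = f"mzspec:{spec.accession}:{run_path}"
        manifest.expected_records[mri] = fields
    manifest.discarded = not manifest.expected_links
    return manifest


# -- MTBLS dialect ----------------------------------------------------------


def _isa_row(cells: list[str]) -> str:
    return "\t".join(f'"{c}"' for c in cells)


def _generate_mtbls(spec: StudySpec, out: Path) -> StudyManifest:
    rng = random.Random(spec.seed)
    manifest = StudyManifest(spec.accession, spec.repository)
    organism_raw, organism_term = ORGANISMS[spec.organism]
    body_raw, body_term = BODY_PARTS[spec.body_part]
    instrument_raw, instrument_term = INSTRUMENTS[spec.instrument]
    taxid = organism_term.split("|", 1)[0]

    (out / "i_Investigation.txt").write_text(
        'Study Identifier\t"{0}"\nStudy Title\t"Synthetic ISA fixture"\n'.format(spec.accession),
        encoding="utf-8")

    tokens = _tokens(rng, spec.n_samples)
    sample_header = ["Sample Name",
                     "Characteristics[Organism]", "Term Source REF", "Term Accession Number",
                     "Characteristics[Organism part]", "Term Source REF", "Term Accession Number",
                     "Factor Value[gender]"]
    assay_header = ["Sample Name", "Parameter Value[Instrument]", "Raw Spectral Data File"]
    sample_lines = ["\t".join(f'"{c}"' for c in sample_header)]
    assay_lines = ["\t".join(f'"{c}"' for c in assay_header)]

    for i, token in enumerate(tokens):
        sample = f"{spec.accession}_sample{i + 1:02d}"
        sex = "female" if i % 2 == 0 else "male"
        sample_lines.append(_isa_row([
            sample, organism_raw, "NCBITAXON",
            f"http://purl.obolibrary.org/obo/NCBITaxon_{taxid}",
            body_raw.lower(), "UBERON", "", sex]))
        run_path = f"FILES/{token}.mzML"
        assay_lines.append(_isa_row([sample, instrument_raw, run_path]))
        if i < spec.vendor_duplicates:
            assay_lines.append(_isa_row([sample, instrument_raw, f"FILES/{token}.raw"]))
        scan_spec = _scan_spec_for(Polarity.POSITIVE, rng)
        generate_mzml(scan_spec, out / run_path)
        manifest.scan_specs[run_path] = scan_spec
        manifest.expected_links[run_path] = (Tier.FULL_PATH.value, sample)
        mri = f"mzspec:{spec.accession}:{run_path}"
        manifest.expected_records[mri] = {
            "NCBITaxonomy": organism_term,
            "UBERONBodyPartName": body_term,
            "BiologicalSex": sex,
            "SampleType": "biological",
            "MassSpectrometer": instrument_term,
        }

    (out / f"s_{spec.accession}.txt").write_text("\n".join(sample_lines) + "\n", encoding="utf-8")
    (out / f"a_{spec.accession}_pos.txt").write_text("\n".join(assay_lines) + "\n", encoding="utf-8")
    return manifest


# -- ReDU-native (GNPS) dialect --------------------------------------------


def _generate_gnps(spec: StudySpec, out: Path) -> StudyManifest:
    rng = random.Random(spec.seed)
    manifest = StudyManifest(spec.accession, spec.repository)
    _organism_raw, organism_term = ORGANISMS[spec.organism]
    _body_raw, body_term = BODY_PARTS[spec.body_part]
    tokens = _tokens(rng, spec.n_samples)

    lines = ["filename\tNCBITaxonomy\tUBERONBodyPartName\tSampleType\tYearOfAnalysis"]
    for token in tokens:
        run_path = f"peak/{token}.mzML"
        lines.append(f"{run_path}\t{organism_term}\t{body_term}\tbiological\t{spec.year}")
        scan_spec = _scan_spec_for(Polarity.POSITIVE, rng)
        generate_mzml(scan_spec, out / run_path)
        manifest.scan_specs[run_path] = scan_spec
        manifest.expected_links[run_path] = (Tier.FULL_PATH.value, run_path)
        mri = f"mzspec:{spec.accession}:{run_path}"
        manifest.expected_records[mri] = {
            "NCBITaxonomy": organism_term,
            "UBERONBodyPartName": body_term,
            "SampleType": "biological",
            "YearOfAnalysis": str(spec.year),
        }
    (out / "redu_metadata.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest


def generate_study(spec: StudySpec, out_dir) -> StudyManifest:
    """Materialize one synthetic study folder and return its manifest."""
    out = Path(out_dir) / spec.accession
    out.mkdir(parents=True, exist_ok=True)
    if spec.repository == "NMDR":
        return _generate_nmdr(spec, out)
    if spec.repository == "MTBLS":
        return _generate_mtbls(spec, out)
    if spec.repository == "GNPS/MassIVE":
        return _generate_gnps(spec, out)
    raise ValueError(f"unknown repository {spec.repository!r}")


def demo_specs(seed: int = 0) -> list[StudySpec]:
    """The three-study demo mini-repository, one study per dialect."""
    return [
        StudySpec(repository="NMDR", accession="ST000001", seed=seed,
                  tier_plan=(Tier.FULL_PATH, Tier.BASE_NAME, Tier.BASE_NAME_NO_EXT,
                             Tier.SEPARATOR_SPLIT, Tier.SUBSTRING),
                  n_unlinked=1,
                  analyses=(Polarity.POSITIVE, Polarity.NEGATIVE)),
        StudySpec(repository="MTBLS", accession="MTBLS1001", seed=seed + 1,
                  n_samples=3, vendor_duplicates=1, organism=1, body_part=1,
                  instrument=1),
        StudySpec(repository="GNPS/MassIVE", accession="MSV000090001",
                  seed=seed + 2, n_samples=2, body_part=0),
    ]


def generate_demo_repository(root, seed: int = 0) -> dict[str, StudyManifest]:
    """Write the demo mini-repository; returns manifests keyed by accession."""
    manifests = {}
    for spec in demo_specs(seed):
        manifests[spec.accession] = generate_study(spec, root)
    return manifests


# ---------------------------------------------------------------------------
# Randomized linkage problems for the brute-force oracle


def random_linkage_problem(rng: random.Random) -> tuple[list[str], dict[str, list[str]]]:
    """Draw a small file/descriptor problem (≤10 × ≤10) for oracle tests.

    Descriptors mix every style the cascade must handle: full paths, base
    names, stripped extensions, separator-packed lists, fragments, junk,
    and deliberate duplicates across samples.
    """
    n_files = rng.randint(1, 10)
    n_samples = rng.randint(1, 10)
    stems = [f"{rng.choice(['run', 'smp', 'qc'])}_{rng.randrange(16**6):06x}"
             for _ in range(n_files)]
    files = [f"{rng.choice(['', 'raw/', 'data/pos/'])}{stem}.{rng.choice(['mzML', 'mzXML', 'raw'])}"
             for stem in stems]
    samples = {f"S{i:02d}": [] for i in range(n_samples)}
    sample_ids = list(samples)
    for sample_id in sample_ids:
        for _ in range(rng.randint(0, 3)):
            style = rng.randrange(8)
            target = rng.choice(files)
            base = target.rsplit("/", 1)[-1]
            stem = base.rsplit(".", 1)[0]
            if style == 0:
                samples[sample_id].append(target)
            elif style == 1:
                samples[sample_id].append(base)
            elif style == 2:
                samples[sample_id].append(stem)
            elif style == 3:
                samples[sample_id].append(stem + "." + rng.choice(["raw", "wiff", "d"]))
            elif style == 4:
                others = [rng.choice(files).rsplit("/", 1)[-1] for _ in range(rng.randint(1, 2))]
                sep = rng.choice([", ", "; ", "|"])
                samples[sample_id].append(sep.join([base] + others))
            elif style == 5:
                lo = rng.randrange(max(1, len(stem) - 4))
                samples[sample_id].append(stem[lo: lo + rng.randint(4, 6)])
            elif style == 6:
                samples[sample_id].append(f"junk_{rng.randrange(1000)}")
            else:
                donor = samples[rng.choice(sample_ids)]
                if donor:
                    samples[sample_id].append(rng.choice(donor))
    return files, samples
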