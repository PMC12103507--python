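# reduharm

Cross-repository harmonization of public metabolomics metadata.

The three major untargeted-metabolomics repositories describe the same
things in incompatible ways: MetaboLights (MTBLS) uses the tabular ISA
framework, Metabolomics Workbench's National Metabolomics Data Repository
(NMDR) uses the sectioned key–value mwTab format, and GNPS/MassIVE uses
optional ReDU-style controlled tables. Finding "all public human urine
runs", or associating a deposited raw file with the sample that produced
it, therefore requires repository-specific plumbing that most groups
rebuild from scratch.

`reduharm` implements that plumbing once, as a library plus a small CLI,
for anyone doing repository-scale reanalysis:

- **MS Run Identifiers (MRIs)** — `mzspec:<accession>:<path>`, the
  dataset-and-file-path subset of the Universal Spectrum Identifier (USI)
  standard — as the universal key for every raw file (mzML, mzXML, .raw,
  .wiff, .cdf, .d) in any of the three repositories.
- **Dialect ingestion**: mwTab documents (sections, sample/factor rows,
  ion mode) and ISA-Tab study folders (investigation/sample/assay tables
  with ontology-annotation triplets), plus native controlled tables.
- **Record linkage**: a five-tier matching cascade associating raw files
  with the sample descriptors submitters actually deposited — full path,
  base name, base name without extension, separator-split multi-file
  cells, and guarded substring matching — accepting only unambiguous
  links; when a study deposited several analyses, files are assigned to
  analyses by reconciling the declared ion mode with the polarity observed
  in each file's scan headers.
- **Vocabulary translation**: free text → controlled terms through curated
  translation sheets and flat ontology snapshots (body parts, plant parts,
  cell types, diseases, instruments, NCBI taxa as `taxid|name`, e.g.
  `9606|Homo sapiens`); unmapped terms are exported for curation, never
  silently passed through.
- **One validated table**: a row per raw file, accepted only if it carries
  at least one piece of sample-descriptive metadata (organism, body part,
  or sample type — a solvent blank counts), validated against a packaged
  schema registry, serialized deterministically (round-trip safe), with
  SDRF export.
- **Retrieval**: batch download of MRIs through an integrity-checked local
  cache with atomic writes, self-healing of corrupted entries, and a
  per-file outcome report.

## Worked example

`examples/02_harmonize_demo.py` generates a three-study synthetic
mini-repository (one study per dialect, with known ground truth),
harmonizes it, and queries the result:

```text
MSV000090001   dialect=GNPS/MassIVE records=2 accepted_links=n/a
MTBLS1001      dialect=MTBLS        records=3 accepted_links=n/a
ST000001       dialect=NMDR         records=5 accepted_links=5

wrote 10 records to redu_table.tsv
human urine runs (7):
  mzspec:MSV000090001:peak/dffxktqn.mzML
  ...
  mzspec:ST000001:raw/27qd9afz.mzML
```

The NMDR study contributes five records — one per linkage tier, each
recovered from a differently-mangled descriptor — and the conjunctive
query `NCBITaxonomy=9606|Homo sapiens AND UBERONBodyPartName=urine`
returns exactly the seven planted human-urine runs (the MTBLS study is
mouse plasma and is excluded). `examples/04_link_files_to_samples.py`
shows the cascade itself:

```text
accepted  raw/pos/plasma_A1.mzML   → Sample_A  via full_path
accepted  plasma_B2.mzML           → Sample_B  via base_name_no_ext
accepted  batch1_C3.mzML           → Sample_C  via separator_split
accepted  batch1_C4.mzML           → Sample_C  via separator_split
accepted  longrun_D5.mzML          → Sample_D  via substring
ambiguous shared.mzML              (excluded: claimed by several samples)
unlinked  mystery.mzML
```

The same functionality is available from the shell:

```sh
reduharm make-fixtures demo/            # materialize the demo repository
reduharm harmonize demo/ --out out/     # table + linkage report + log
reduharm query out/redu_table.tsv --filter 'NCBITaxonomy=9606|Homo sapiens'
reduharm scan-stats out/../demo/ST000001/raw/*.mzML
reduharm fetch mris.txt --backend-root demo/ --cache cache/
```

## Layout

- `src/reduharm/` — the library (`identifiers`, `mwtab_ingest`,
  `mtbls_ingest`, `vocabulary`, `linker`, `msdata`, `redu_schema`,
  `retrieval`, `fixtures`, `pipeline`, `cli`); packaged registries under
  `src/reduharm/data/`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, rules, parameters, and design decisions.
- `tests/` — unit, property, and end-to-end acceptance tests.
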