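# Methods

This note documents the rules the harmonizer implements, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Identifiers

An MS Run Identifier (MRI) is `mzspec:<accession>:<path>`: the USI scheme
prefix, a dataset accession, and a slash-separated relative file path. The
string is split at its first two colons, so a bare colon in a path is a
parse error; paths containing colons must be percent-encoded (spaces pass
through unencoded — a local convention, since submitted paths routinely
contain them). Scan-level USIs (`...:scan:17`, `...:index:n`) are accepted
and truncated to their MRI. Path validation rejects empty, absolute, and
`..`-containing paths.

Repository dispatch uses anchored accession patterns — `MSV\d{9}`
(GNPS/MassIVE), `MTBLS\d+` (MetaboLights), `ST\d{6}` (Metabolomics
Workbench/NMDR) — kept in a registry argument so accession drift or a new
repository needs no code change. The patterns are mutually exclusive;
classification either returns exactly one repository or raises.

Supported raw formats are mzML, mzXML, .raw, .wiff, .cdf, and .d, matched
case-insensitively on the terminal extension; `.d` is a directory-style
format but is treated as a suffix like the others.

## mwTab ingestion

Documents must carry the `#METABOLOMICS WORKBENCH` header (fatal if
absent); everything else is lenient: unknown sections are preserved,
malformed key lines are logged as warnings and skipped. Both `KEY<TAB>value`
and `KEY:value` entry styles are accepted, first delimiter wins.
`SUBJECT_SAMPLE_FACTORS` rows carry `key:value | key:value` factors and
`key=value | key=value` additional data. Pair separators are `|`, not
`;` — deliberately, because additional-data values legitimately contain
`;`-joined raw-file lists which must reach the linker unsplit.

Ion mode is read from the MS section (`ION_MODE`); accepted spellings are
{positive, pos, esi+, +} and {negative, neg, esi-, −, -},
case-insensitive; anything else is *unspecified*, which disqualifies the
analysis from polarity disambiguation rather than raising.

Per-sample raw-file descriptors are gathered in priority order: the
repository's REST file table when supplied, then named raw-file keys in
the additional data (`RAW_FILE_NAME`, `RAW_DATA_FILE`, `DATAFILE`), then
remaining additional-data values, factor values, and finally the sample
identifier itself. All values are kept: non-filename values (ages,
treatments) are harmless because exact tiers require equality and the
substring tier is length- and uniqueness-guarded.

## ISA-Tab ingestion and column mapping

Tables are read positionally (stdlib `csv`, tab-delimited, quoted) because
ISA headers repeat: every ontology-annotated column is followed by
`Term Source REF` / `Term Accession Number`, and that positional triplet
association must survive parsing. Assay rows naming a sample absent from
the sample table are flagged orphaned, never silently dropped; ragged rows
are padded with a warning.

Column equivalences map MetaboLights names to harmonized columns
(`Organism` → NCBITaxonomy, `Organism part` → UBERONBodyPartName,
`Instrument` → MassSpectrometer, ...), with submitter-named fallbacks
searched in both `Factor Value[...]` and `Characteristics[...]` wrappers,
case-insensitive on the inner term (e.g. `sex` / `gender` →
BiologicalSex). The shipped registry covers the documented mappings plus
common fallbacks and is user-extensible via TSV. When a taxonomy cell
carries a resolvable NCBITaxon accession, the `taxid|name` form is built
from the accession directly, bypassing name lookup.

When a run was deposited in several formats, only the open copy is kept:
files sharing a base name modulo one extension (case-insensitive) are one
run, and vendor copies are removed iff an mzML/mzXML sibling exists. The
pass is idempotent and never removes a file without an open sibling.

## Vocabulary translation

Resolution order for a raw term: exact translation-sheet entry → ontology
canonical/synonym lookup → substring sheet entry. The order is a design
decision (documented here because sheet and ontology can both match): a
curated exact mapping should override everything, and a canonical ontology
term should beat a loose substring rule. Substring patterns must be ≥ 3
characters, are matched case-insensitively on whitespace-collapsed text,
and the longest pattern wins, ties broken lexicographically — so the
answer is independent of sheet row order. Terms already in harmonized
`taxid|name` form pass through. Anything unresolved becomes an explicit
`Unmapped` marker and is exported to a review TSV, mirroring the manual
curation loop such pipelines require.

Ontology registries are flat TSV snapshots (term, identifier, synonyms)
for body parts, plant parts, cell types, diseases, instruments, and taxa.
They are deliberately small curated extracts, not full ontologies — flat
synonym lookup is all the procedure needs, and the snapshots are
user-replaceable.

## The linkage cascade

Tiers, strictly in order, all comparisons case-insensitive:

1. `full_path` — descriptor equals the deposited path;
2. `base_name` — base file names equal;
3. `base_name_no_ext` — base names equal after stripping one extension;
4. `separator_split` — descriptors split on `,`, `;`, `|` (configurable)
   and the parts re-run through tiers 1–3;
5. `substring` — descriptor contained in the file's extension-stripped
   base name or vice versa; the contained string must be ≥ 4 characters,
   and the link must be unique across samples *and* across files.

The first tier that yields any match for a file decides that file: a
unique sample is accepted, two or more samples make the file ambiguous and
excluded. The separator set includes `|` as the third delimiter; it is an
argument, so deployments can change it. A study with zero accepted links
is discarded entirely.

The ≥ 4-character substring guard and the cross-file uniqueness rule exist
to prevent trivial-fragment explosions (a descriptor like `run_` matching
every file); files failing either guard are reported ambiguous, which is
the conservative reading of "accept only unambiguous matches".

### Polarity disambiguation

When a study deposited several analyses, per-file scan polarities decide
which analysis' technical metadata a file may use: a uniformly-positive
file maps to the unique positive analysis, and so on. Files with mixed or
unreadable polarity, and analyses with unspecified ion mode, are
compatible with nothing; any file with zero or ≥ 2 compatible analyses
has its analysis-level metadata dropped while sample-level metadata
(organism, body part, sex) survives — provided every analysis of the
study agrees on those values. Single-analysis studies bypass the step.

## Scan summaries

mzML is read with a streaming lxml scan of `<spectrum>` elements, taking
`ms level` (MS:1000511) and polarity (MS:1000130/MS:1000129) from cvParams
wherever nested; peak arrays are never decoded, so memory per file is
constant. mzXML goes through pyteomics (`msLevel`, `polarity` attribute).
Polarity is per spectrum — file-level defaults are not assumed, because
mixed-polarity files exist and drive disambiguation. MS levels are kept
distinct; "has MS/MS" means any scan with level ≥ 2. Integrity of an
mzML/mzXML file means well-formed XML with the root element its extension
implies; gzipped and indexed-mzML variants are accepted.

## The harmonized table

The schema ships as a packaged TSV (column order, validation kind per
column) together with allowed-term lists; vocabulary-controlled columns
additionally accept all terms of the ontology registries feeding them, so
translation output validates by construction. A candidate record is
accepted iff at least one sample-descriptive field — NCBITaxonomy,
UBERONBodyPartName, or SampleType (blank/QC designations included) — is
populated; technical metadata alone never qualifies. A malformed MRI is a
structural error, distinct from a metadata rejection.

Missing cells serialize as the explicit token `missing value` (never empty
cells — downstream filters handle explicit fillers reliably); coordinates
as `lat|lon` decimal degrees, consistent with the `taxid|name` pipe
convention. `read_table ∘ write_table` is the identity, provenance
included (provenance identifiers travel in a dedicated column). SDRF
export is a header mapping (`characteristics[organism]` etc.), nothing
more.

For NMDR records, SampleType defaults to `biological` when an organism or
body part resolved but no explicit blank/QC designation was found — blanks
are expected to be declared, biological samples usually are not.
YearOfAnalysis is taken from the first four-digit year in
`PROJECT_DATE`/`SUBMIT_DATE` of the assigned analysis.

## Retrieval

Cache keys are `accession/run_path` — content addressing was rejected
because repositories do not publish digests. A cached mzML/mzXML is valid
iff it passes the XML integrity check; for vendor/cdf payloads only a
non-empty check is possible (documented as weaker). Downloads are written
to a temp file and atomically renamed, so interrupted transfers are never
visible as cache entries. Every requested MRI gets exactly one outcome
(`cache_hit`, `downloaded`, `integrity_failed_then_redownloaded`, or
`error` with a reason); a failing file never aborts the batch. Conversion
of vendor formats is out of scope: `request_conversion` returns a 30-day
ticket and delegates to an injected converter interface. HTTP adapters for
the live repositories exist but are excluded from the test surface; the
filesystem mock backend is the tested contract.

## Synthetic data

The generator emulates the *structural* heterogeneity the harmonizer must
survive: mwTab studies whose descriptors force each cascade tier (full
path, bare base name, wrong extension, `;`-packed cells, name fragments),
dual-polarity and same-polarity analysis pairs, deliberately ambiguous
duplicate descriptors, ISA studies with vendor/open duplicate files and
submitter-named factor columns, and schema-minimal mzML/mzXML files with
exact MS-level/polarity plans (1-point dummy peak arrays keep files tiny).
File stems are fixed-length random tokens, which guarantees planted
substring fragments are unique and no stem accidentally contains another.

It does **not** emulate realistic spectra, real-world descriptor noise
beyond these constructions (typos, locale encodings), repository API
behavior, or production-scale study sizes. Passing tests therefore show
the rules are implemented exactly as stated and are stable under the
constructions the rules were designed for — not that real-repository
recovery rates will match the synthetic 100%.

Default study conditions: demo studies use 2–6 files/samples per study,
one study per dialect; randomized linkage problems are bounded at ≤ 10
files × ≤ 10 samples so the exhaustive brute-force reference stays
trivially correct; the acceptance script uses 500 such problems, 20
planted-tier studies, and 100 scan-spec round trips per dialect. These
sizes exercise every rule path; the algorithms are O(files × descriptors)
per tier and scale linearly beyond them.

## Known limitations

- Matching is exact/substring only; no edit-distance recovery of typo'd
  descriptors (deliberately — fuzzy links are how wrong metadata spreads).
- Translation coverage is bounded by the shipped sheets/snapshots; real
  deployments are expected to merge their own TSVs over the packaged ones.
- The schema registry covers the documented columns plus common ReDU
  variables; it is extensible by editing a TSV, not code.
- Encoding handling is UTF-8 with a latin-1 fallback, not full charset
  detection.
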