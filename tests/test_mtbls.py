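"""ISA-Tab parsing, column equivalence mapping, open-format preference."""

import random

import pytest

from reduharm import mtbls_ingest as mt


def _write_study(tmp_path, sample_rows, assay_rows,
                 sample_header=None, assay_header=None):
    sample_header = sample_header or [
        "Sample Name",
        "Characteristics[Organism]", "Term Source REF", "Term Accession Number",
        "Characteristics[Organism part]", "Term Source REF", "Term Accession Number",
        "Factor Value[gender]"]
    assay_header = assay_header or ["Sample Name", "Parameter Value[Instrument]",
                                    "Raw Spectral Data File"]
    (tmp_path / "i_Investigation.txt").write_text(
        'Study Identifier\t"MTBLS777"\n', encoding="utf-8")

    def fmt(rows, header):
        lines = ["\t".join(f'"{c}"' for c in header)]
        lines += ["\t".join(f'"{c}"' for c in row) for row in rows]
        return "\n".join(lines) + "\n"

    (tmp_path / "s_study.txt").write_text(fmt(sample_rows, sample_header), encoding="utf-8")
    (tmp_path / "a_assay.txt").write_text(fmt(assay_rows, assay_header), encoding="utf-8")
    return tmp_path


@pytest.fixture()
def study(tmp_path):
    folder = _write_study(
        tmp_path,
        sample_rows=[
            ["S1", "Homo sapiens", "NCBITAXON",
             "http://purl.obolibrary.org/obo/NCBITaxon_9606",
             "urine", "UBERON", "", "female"],
            ["S2", "Homo sapiens", "NCBITAXON",
             "http://purl.obolibrary.org/obo/NCBITaxon_9606",
             "urine", "UBERON", "", "male"],
        ],
        assay_rows=[
            ["S1", "Q Exactive", "FILES/run1.mzML"],
            ["S2", "Q Exactive", "FILES/run2.mzML"],
            ["S99", "Q Exactive", "FILES/run3.mzML"],  # orphaned sample ref
        ],
    )
    return mt.parse_isatab(folder)


class TestParseIsatab:
    def test_study_identifier_from_investigation(self, study):
        assert study.study_id == "MTBLS777"

    def test_sample_values_by_column_name(self, study):
        idx = study.sample_table.column_index("Characteristics[Organism]")
        assert study.sample_table.value(study.sample_table.rows[0], idx) == "Homo sapiens"

    def test_ontology_triplet_stays_with_parent_column(self, study):
        idx = study.sample_table.column_index("Characteristics[Organism]")
        term, source, accession = study.sample_table.ontology_triplet(
            study.sample_table.rows[0], idx)
        assert (term, source) == ("Homo sapiens", "NCBITAXON")
        assert accession.endswith("NCBITaxon_9606")

    def test_orphaned_assay_row_is_flagged_not_dropped(self, study):
        assert [o[2] for o in study.orphaned] == ["S99"]
        assert len(study.assay_tables[0].rows) == 3

    def test_missing_sample_table_is_structured_error(self, tmp_path):
        (tmp_path / "a_only.txt").write_text("Sample Name\n", encoding="utf-8")
        with pytest.raises(mt.IsaTabError):
            mt.parse_isatab(tmp_path)

    def test_two_assay_files_give_two_tables(self, tmp_path):
        folder = _write_study(tmp_path, [["S1", "Homo sapiens", "", "", "urine", "", "", "f"]],
                              [["S1", "QE", "a.mzML"]])
        (tmp_path / "a_assay_neg.txt").write_text(
            '"Sample Name"\t"Raw Spectral Data File"\n"S1"\t"b.mzML"\n', encoding="utf-8")
        assert len(mt.parse_isatab(folder).assay_tables) == 2

    def test_ragged_row_padded_with_warning(self, tmp_path):
        (tmp_path / "i_x.txt").write_text('Study Identifier\t"MTBLS1"\n')
        (tmp_path / "s_x.txt").write_text('"Sample Name"\t"Organism"\n"S1"\n')
        (tmp_path / "a_x.txt").write_text('"Sample Name"\n"S1"\n')
        parsed = mt.parse_isatab(tmp_path)
        assert parsed.sample_table.rows == [["S1", ""]]
        assert parsed.sample_table.warnings


class TestMapColumns:
    def test_quoted_equivalences(self, study):
        mapped = mt.map_columns(study)
        fields = mapped["FILES/run1.mzML"]
        # accession resolves taxonomy straight to taxid|name form
        assert fields["NCBITaxonomy"] == "9606|Homo sapiens"
        assert fields["UBERONBodyPartName"] == "urine"
        assert fields["MassSpectrometer"] == "Q Exactive"

    def test_gender_factor_fallback(self, study):
        mapped = mt.map_columns(study)
        assert mapped["FILES/run1.mzML"]["BiologicalSex"] == "female"
        assert mapped["FILES/run2.mzML"]["BiologicalSex"] == "male"

    def test_absent_column_leaves_field_unset(self, tmp_path):
        folder = _write_study(
            tmp_path,
            sample_rows=[["S1", "x"]],
            assay_rows=[["S1", "f.mzML"]],
            sample_header=["Sample Name", "Comment[note]"],
            assay_header=["Sample Name", "Raw Spectral Data File"],
        )
        mapped = mt.map_columns(mt.parse_isatab(folder))
        assert "BiologicalSex" not in mapped["f.mzML"]
        assert "" not in mapped["f.mzML"].values()

    def test_empty_registry_rejected(self, study):
        with pytest.raises(ValueError):
            mt.map_columns(study, equivalences=())


class TestPreferOpenFormat:
    @pytest.mark.parametrize("files,expected", [
        (["a.raw", "a.mzML", "b.raw"], ["a.mzML", "b.raw"]),
        (["a.mzML", "a.mzXML"], ["a.mzML", "a.mzXML"]),  # no vendor involved
        ([], []),
        (["x/A.RAW", "y/a.mzml"], ["y/a.mzml"]),          # case-insensitive pairing
        (["a.wiff", "a.d", "a.mzXML"], ["a.mzXML"]),
        (["only.raw"], ["only.raw"]),                     # no open sibling: untouched
    ])
    def test_vendor_siblings_removed(self, files, expected):
        assert mt.prefer_open_format(files) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_and_conservative(self, seed):
        rng = random.Random(seed)
        stems = [f"s{i}" for i in range(rng.randint(1, 6))]
        files = []
        for stem in stems:
            for ext in rng.sample(["mzML", "mzXML", "raw", "wiff", "d", "cdf"],
                                  rng.randint(1, 4)):
                files.append(f"{stem}.{ext}")
        once = mt.prefer_open_format(files)
        assert mt.prefer_open_format(once) == once
        # a removed file always has an open-format sibling with the same stem
        for gone in set(files) - set(once):
            stem = gone.rsplit(".", 1)[0]
            assert any(f.rsplit(".", 1)[0] == stem and
                       f.rsplit(".", 1)[1].lower() in ("mzml", "mzxml") for f in once)
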