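"""Acceptance rule, table validation, serialization round trip, SDRF export."""

import itertools
import random

import pytest

from reduharm import redu_schema as rs
from reduharm.identifiers import MriError, make_mri

MRI = "mzspec:ST000001:raw/a.mzML"


class TestAcceptRecord:
    def test_organism_alone_suffices(self):
        got = rs.accept_record({"MRI": MRI, "NCBITaxonomy": "9606|Homo sapiens"})
        assert isinstance(got, rs.ReduRecord)

    def test_blank_sample_type_suffices(self):
        got = rs.accept_record({"MRI": MRI, "SampleType": "blank_extraction"})
        assert isinstance(got, rs.ReduRecord)

    def test_technical_metadata_alone_is_rejected(self):
        got = rs.accept_record({"MRI": MRI, "MassSpectrometer": "Q Exactive",
                                "ChromatographyAndPhase": "reverse phase (C18)"})
        assert isinstance(got, rs.Rejection)
        assert "sample-descriptive" in got.reason

    def test_invalid_mri_is_structural_error_not_rejection(self):
        with pytest.raises(MriError):
            rs.accept_record({"MRI": "not-an-mri", "NCBITaxonomy": "9606|Homo sapiens"})

    def test_filler_token_does_not_count_as_populated(self):
        got = rs.accept_record({"MRI": MRI, "NCBITaxonomy": rs.MISSING})
        assert isinstance(got, rs.Rejection)

    def test_descriptive_power_set_exhaustively(self):
        """Accepted iff ≥1 of organism/body part/sample type is populated."""
        values = {"NCBITaxonomy": "9606|Homo sapiens",
                  "UBERONBodyPartName": "urine",
                  "SampleType": "blank_QC"}
        for present in itertools.chain.from_iterable(
                itertools.combinations(values, k) for k in range(4)):
            candidate = {"MRI": MRI, "MassSpectrometer": "Q Exactive"}
            candidate.update({k: values[k] for k in present})
            got = rs.accept_record(candidate)
            if present:
                assert isinstance(got, rs.ReduRecord), present
            else:
                assert isinstance(got, rs.Rejection), present


def _record(accession="ST000001", path="raw/a.mzML", **fields):
    return rs.ReduRecord(mri=make_mri(accession, path), fields=fields)


class TestValidateTable:
    def test_duplicate_mri_detected(self):
        table = rs.ReduTable(records=[_record(NCBITaxonomy="9606|Homo sapiens"),
                                      _record(NCBITaxonomy="9606|Homo sapiens")])
        report = rs.validate_table(table)
        assert any(f.message == "duplicate MRI" for f in report.failures)

    def test_taxonomy_without_taxid_prefix_fails(self):
        table = rs.ReduTable(records=[_record(NCBITaxonomy="Homo sapiens")])
        report = rs.validate_table(table)
        assert [f.column for f in report.failures] == ["NCBITaxonomy"]
        assert "taxid|name" in report.failures[0].message

    def test_vocabulary_violation_reported_with_value(self):
        table = rs.ReduTable(records=[_record(SampleType="weird stuff")])
        report = rs.validate_table(table)
        assert report.failures[0].value == "weird stuff"

    def test_empty_table_is_valid(self):
        assert rs.validate_table(rs.ReduTable()).ok

    @pytest.mark.parametrize("column,value,ok", [
        ("YearOfAnalysis", "2021", True),
        ("YearOfAnalysis", "1492", False),
        ("LatitudeandLongitude", "32.7|-117.2", True),
        ("LatitudeandLongitude", "200|0", False),
        ("UBERONBodyPartName", "urine", True),
        ("UBERONBodyPartName", "T cell", True),  # cell-type registry feeds it
    ])
    def test_kind_checks(self, schema, column, value, ok):
        assert (schema.check_value(column, value) is None) is ok


def _random_table(rng: random.Random) -> rs.ReduTable:
    accessions = ["ST000001", "MTBLS5", "MSV000090123"]
    organisms = ["9606|Homo sapiens", "10090|Mus musculus", None]
    parts = ["urine", "blood plasma", "liver", None]
    table = rs.ReduTable()
    for i in range(rng.randint(1, 12)):
        fields = {}
        organism = rng.choice(organisms)
        part = rng.choice(parts)
        if organism:
            fields["NCBITaxonomy"] = organism
        if part:
            fields["UBERONBodyPartName"] = part
        if not fields:
            fields["SampleType"] = "blank_QC"
        if rng.random() < 0.5:
            fields["YearOfAnalysis"] = str(rng.randint(2000, 2024))
        if rng.random() < 0.3:
            fields["BiologicalSex"] = rng.choice(["male", "female"])
        if rng.random() < 0.3:
            fields["LatitudeandLongitude"] = f"{rng.uniform(-90, 90):.3f}|{rng.uniform(-180, 180):.3f}"
        accession = rng.choice(accessions)
        record = rs.ReduRecord(mri=make_mri(accession, f"raw/f{i:03d}.mzML"), fields=fields)
        table.records.append(record)
        if rng.random() < 0.7:
            table.provenance[rs.format_mri(record.mri)] = f"AN{i:06d}"
    return table


class TestSerialization:
    @pytest.mark.parametrize("seed", range(15))
    def test_round_trip_identity(self, tmp_path, seed):
        """read(write(table)) == table, missing-value cells included."""
        table = _random_table(random.Random(seed))
        out = tmp_path / "table.tsv"
        rs.write_table(table, out)
        back = rs.read_table(out)
        assert [(rs.format_mri(r.mri), r.fields) for r in back.records] == \
               [(rs.format_mri(r.mri), r.fields) for r in table.records]
        assert back.provenance == table.provenance

    def test_missing_cells_use_filler_token(self, tmp_path):
        table = rs.ReduTable(records=[_record(NCBITaxonomy="9606|Homo sapiens")])
        out = tmp_path / "t.tsv"
        rs.write_table(table, out)
        header, row = out.read_text().splitlines()
        cells = dict(zip(header.split("\t"), row.split("\t")))
        assert cells["BiologicalSex"] == rs.MISSING
        assert cells["NCBITaxonomy"] == "9606|Homo sapiens"

    def test_write_is_deterministic(self, tmp_path):
        table = _random_table(random.Random(7))
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        rs.write_table(table, a)
        rs.write_table(table, b)
        assert a.read_bytes() == b.read_bytes()

    def test_invalid_table_refused(self, tmp_path):
        table = rs.ReduTable(records=[_record(NCBITaxonomy="no taxid")])
        with pytest.raises(ValueError, match="failed validation"):
            rs.write_table(table, tmp_path / "x.tsv")


def test_sdrf_export_header_mapping(tmp_path):
    table = rs.ReduTable(records=[_record(NCBITaxonomy="9606|Homo sapiens",
                                          BiologicalSex="female")])
    out = tmp_path / "table.sdrf.tsv"
    rs.write_sdrf(table, out)
    header, row = out.read_text().splitlines()
    assert "characteristics[organism]" in header.split("\t")
    assert "9606|Homo sapiens" in row.split("\t")
    assert row.split("\t")[0] == MRI
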