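"""Term translation: resolution order, determinism, schema validity."""

import random

import pytest

from reduharm import vocabulary as vocab
from reduharm.redu_schema import default_schema


class TestFormatTaxonomy:
    @pytest.mark.parametrize("taxid,name,expected", [
        (9606, "Homo sapiens", "9606|Homo sapiens"),
        (10090, "Mus musculus", "10090|Mus musculus"),
    ])
    def test_pipe_form(self, taxid, name, expected):
        assert vocab.format_taxonomy(taxid, name) == expected

    @pytest.mark.parametrize("taxid,name", [(0, "x"), (-5, "x"), (9606, "  ")])
    def test_invalid_inputs(self, taxid, name):
        with pytest.raises(ValueError):
            vocab.format_taxonomy(taxid, name)


class TestTranslateTerm:
    def test_taxonomy_via_ontology(self, sheet, registries):
        assert vocab.translate_term("Homo sapiens", "NCBITaxonomy", sheet, registries) \
            == "9606|Homo sapiens"

    def test_case_insensitive(self, sheet, registries):
        assert vocab.translate_term("homo sapiens", "NCBITaxonomy", sheet, registries) \
            == "9606|Homo sapiens"

    def test_synonym_resolves_to_canonical(self, sheet, registries):
        assert vocab.translate_term("stool", "UBERONBodyPartName", sheet, registries) \
            == "feces"

    def test_already_harmonized_taxonomy_passes_through(self, sheet, registries):
        assert vocab.translate_term("9606|Homo sapiens", "NCBITaxonomy", sheet, registries) \
            == "9606|Homo sapiens"

    def test_unmapped_is_explicit_marker(self, sheet, registries):
        result = vocab.translate_term("xyzzy material", "UBERONBodyPartName",
                                      sheet, registries)
        assert result == vocab.Unmapped("xyzzy material", "UBERONBodyPartName")

    def test_whitespace_only_raw_rejected(self, sheet, registries):
        with pytest.raises(ValueError):
            vocab.translate_term("   ", "SampleType", sheet, registries)

    def test_resolution_order_ontology_beats_substring_sheet(self, registries):
        # registry synonym "myocardium" and sheet substring "ventricular" both
        # apply; the ontology layer is consulted first and wins.
        sheet = vocab.TranslationSheet([
            vocab.SheetEntry("ventricular", "substring", "heart", "UBERONBodyPartName"),
        ])
        raw = "left ventricular myocardium tissue"
        # brute-force the stated order: exact sheet → ontology → substring
        exact = [e for e in sheet.entries if e.match_mode == "exact"
                 and e.source_pattern.lower() == raw.lower()]
        assert not exact
        ontology_hit = None
        for domain in vocab.COLUMN_DOMAINS["UBERONBodyPartName"]:
            rec = registries[domain].lookup(raw)
            if rec:
                ontology_hit = rec.term
        expected = ontology_hit if ontology_hit else "heart"
        assert vocab.translate_term(raw, "UBERONBodyPartName", sheet, registries) == expected

    def test_exact_sheet_beats_ontology(self, registries):
        sheet = vocab.TranslationSheet([
            vocab.SheetEntry("urine", "exact", "blood plasma", "UBERONBodyPartName"),
        ])
        assert vocab.translate_term("urine", "UBERONBodyPartName", sheet, registries) \
            == "blood plasma"

    def test_longest_substring_pattern_wins(self, registries):
        sheet = vocab.TranslationSheet([
            vocab.SheetEntry("plasma", "substring", "blood plasma", "UBERONBodyPartName"),
            vocab.SheetEntry("rich plasma", "substring", "blood serum", "UBERONBodyPartName"),
        ])
        assert vocab.translate_term("platelet rich plasma extract", "UBERONBodyPartName",
                                    sheet, registries) == "blood serum"

    @pytest.mark.parametrize("seed", range(10))
    def test_sheet_order_never_changes_answers(self, sheet, registries, seed):
        rng = random.Random(seed)
        shuffled = list(sheet.entries)
        rng.shuffle(shuffled)
        reordered = vocab.TranslationSheet(shuffled)
        for raw, column in [("plasma sample", "UBERONBodyPartName"),
                            ("solvent blank", "SampleType"),
                            ("female", "BiologicalSex"),
                            ("reversed phase LC", "ChromatographyAndPhase")]:
            assert vocab.translate_term(raw, column, sheet, registries) == \
                vocab.translate_term(raw, column, reordered, registries)


def test_every_emitted_term_is_schema_valid(sheet, registries, schema):
    """All translation targets and ontology terms validate for their column."""
    for entry in sheet.entries:
        column = schema.by_name.get(entry.target_column)
        assert column is not None, entry.target_column
        if column.kind == "vocab":
            assert entry.target_term in schema.allowed_terms(entry.target_column), entry
    for column, domains in vocab.COLUMN_DOMAINS.items():
        if schema.by_name[column].kind != "vocab":
            continue
        for domain in domains:
            for term in registries[domain].terms():
                assert schema.check_value(column, term) is None


def test_unmapped_report_written(tmp_path):
    out = tmp_path / "unmapped.tsv"
    vocab.write_unmapped_report(
        [vocab.Unmapped("gloop", "SampleType"), vocab.Unmapped("gloop", "SampleType")], out)
    lines = out.read_text().splitlines()
    assert lines[0] == "column\traw_term\toccurrences"
    assert lines[1] == "SampleType\tgloop\t2"
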