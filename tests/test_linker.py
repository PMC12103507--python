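"""Linkage cascade: tier semantics, ambiguity, oracle equivalence, polarity."""

import random

import pytest

from oracle import brute_force_linkage
from reduharm import fixtures, linker
from reduharm.linker import Tier, associate_files, disambiguate_by_polarity
from reduharm.msdata import ScanSummary
from reduharm.mwtab_ingest import MwTabDocument
from reduharm.polarity import Polarity


def _links(linkage):
    return {a.run_path: (a.tier.value, a.sample_id) for a in linkage.accepted}


class TestCascade:
    def test_full_path_exact_match(self):
        got = associate_files(["data/pos/s1.mzML"], {"A": ["data/pos/s1.mzML"]})
        assert _links(got) == {"data/pos/s1.mzML": ("full_path", "A")}

    def test_separator_split_links_both_files(self):
        got = associate_files(["s1.mzML", "s2.mzML"], {"A": ["s1.raw; s2.raw"]})
        assert _links(got) == {"s1.mzML": ("separator_split", "A"),
                               "s2.mzML": ("separator_split", "A")}

    def test_exact_stem_beats_substring(self):
        # "sample_10" equals the stem of sample_10.mzML, so the file resolves
        # at base_name_no_ext; the fact that "sample_1" is also a substring
        # of the stem never comes into play.
        got = associate_files(["sample_10.mzML"], {"A": ["sample_1"], "B": ["sample_10"]})
        assert _links(got) == {"sample_10.mzML": ("base_name_no_ext", "B")}

    def test_two_proper_substrings_are_ambiguous(self):
        got = associate_files(["sample_10.mzML"], {"A": ["ample_1"], "B": ["mple_10"]})
        assert not got.accepted
        assert [a.run_path for a in got.ambiguous] == ["sample_10.mzML"]
        assert got.ambiguous[0].tier == Tier.SUBSTRING

    def test_two_samples_same_basename_ambiguous(self):
        got = associate_files(["raw/x.mzML"], {"A": ["x.mzML"], "B": ["x.mzML"]})
        assert not got.accepted and got.discarded_study
        assert got.ambiguous[0].ambiguous is True

    def test_substring_fragment_matching_two_files_rejects_both(self):
        got = associate_files(["run_alpha.mzML", "run_beta.mzML"], {"A": ["run_"]})
        assert not got.accepted
        assert {a.run_path for a in got.ambiguous} == {"run_alpha.mzML", "run_beta.mzML"}

    def test_short_substring_descriptor_never_matches(self):
        got = associate_files(["abc.mzML"], {"A": ["abc"]})
        # stem "abc" is below the 4-character guard for the substring tier,
        # but the base-name-no-ext tier still matches exactly
        assert _links(got) == {"abc.mzML": ("base_name_no_ext", "A")}
        got2 = associate_files(["abcdef.mzML"], {"A": ["abc"]})
        assert not got2.accepted and got2.unlinked_files == ["abcdef.mzML"]

    def test_unmatched_files_reported_unlinked(self):
        got = associate_files(["a.mzML", "zz.mzML"], {"A": ["a.mzML"]})
        assert got.unlinked_files == ["zz.mzML"]
        assert not got.discarded_study

    def test_empty_descriptors_discards_study(self):
        got = associate_files(["a.mzML"], {})
        assert got.discarded_study and got.unlinked_files == ["a.mzML"]

    def test_empty_files_rejected(self):
        with pytest.raises(ValueError):
            associate_files([], {"A": ["x"]})

    def test_case_insensitive_matching(self):
        got = associate_files(["RAW/Sample.mzML"], {"A": ["raw/sample.MZML"]})
        assert _links(got) == {"RAW/Sample.mzML": ("full_path", "A")}


class TestProperties:
    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence_on_random_problems(self, seed):
        """Cascade output equals literal brute-force rule application."""
        rng = random.Random(seed)
        files, descriptors = fixtures.random_linkage_problem(rng)
        got = associate_files(files, descriptors)
        exp_links, exp_amb, exp_unlinked = brute_force_linkage(files, descriptors)
        assert _links(got) == exp_links
        assert {a.run_path for a in got.ambiguous} == exp_amb
        assert set(got.unlinked_files) == exp_unlinked

    @pytest.mark.parametrize("seed", range(20))
    def test_adding_descriptor_never_demotes_tier(self, seed):
        """Tier monotonicity: extra descriptors can only raise a file's tier
        (or make it ambiguous), never push it to a lower-priority tier."""
        rng = random.Random(seed + 1000)
        files, descriptors = fixtures.random_linkage_problem(rng)
        before = _links(associate_files(files, descriptors))
        target = rng.choice(sorted(descriptors) or ["S00"])
        descriptors.setdefault(target, []).append(rng.choice(files))
        after = associate_files(files, descriptors)
        order = [t.value for t in Tier]
        after_links = _links(after)
        after_amb = {a.run_path for a in after.ambiguous}
        for run_path, (tier, _sample) in before.items():
            if run_path in after_links:
                assert order.index(after_links[run_path][0]) <= order.index(tier)
            else:
                assert run_path in after_amb

    @pytest.mark.parametrize("seed", range(20))
    def test_accepted_links_are_injective_per_file(self, seed):
        rng = random.Random(seed + 2000)
        files, descriptors = fixtures.random_linkage_problem(rng)
        got = associate_files(files, descriptors)
        paths = [a.run_path for a in got.accepted]
        assert len(paths) == len(set(paths))
        assert not any(a.ambiguous for a in got.accepted)
        # conservation: every file lands in exactly one bucket
        all_paths = paths + [a.run_path for a in got.ambiguous] + got.unlinked_files
        assert sorted(all_paths) == sorted(files)


def _doc(analysis_id, polarity_label):
    doc = MwTabDocument(analysis_id=analysis_id)
    doc.sections["MS"] = {"ION_MODE": polarity_label}
    return doc


def _summary(path, *level_pol_counts):
    s = ScanSummary(run_path=path)
    for level, pol, n in level_pol_counts:
        s.add(level, pol, n)
    return s


class TestPolarityDisambiguation:
    def test_uniform_positive_file_maps_to_positive_analysis(self):
        got = disambiguate_by_polarity(
            [_doc("A1", "POSITIVE"), _doc("A2", "NEGATIVE")],
            [("f.mzML", _summary("f.mzML", (1, Polarity.POSITIVE, 100)))])
        assert got == {"f.mzML": "A1"}

    def test_two_compatible_analyses_drop_the_file(self):
        got = disambiguate_by_polarity(
            [_doc("A1", "POSITIVE"), _doc("A2", "POSITIVE")],
            [("f.mzML", _summary("f.mzML", (1, Polarity.POSITIVE, 10)))])
        assert got == {"f.mzML": linker.DROPPED}

    def test_mixed_polarity_file_dropped(self):
        got = disambiguate_by_polarity(
            [_doc("A1", "POSITIVE"), _doc("A2", "NEGATIVE")],
            [("f.mzML", _summary("f.mzML", (1, Polarity.POSITIVE, 5),
                                 (1, Polarity.NEGATIVE, 5)))])
        assert got == {"f.mzML": linker.DROPPED}

    def test_single_analysis_bypasses_disambiguation(self):
        got = disambiguate_by_polarity(
            [_doc("A1", "POSITIVE")],
            [("f.mzML", _summary("f.mzML", (1, Polarity.NEGATIVE, 3)))])
        assert got == {"f.mzML": "A1"}

    def test_unspecified_analysis_is_never_compatible(self):
        got = disambiguate_by_polarity(
            [_doc("A1", "POSITIVE"), _doc("A2", "")],
            [("pos.mzML", _summary("pos.mzML", (1, Polarity.POSITIVE, 2))),
             ("neg.mzML", _summary("neg.mzML", (1, Polarity.NEGATIVE, 2)))])
        assert got == {"pos.mzML": "A1", "neg.mzML": linker.DROPPED}


def test_linkage_report_tsv(tmp_path):
    got = associate_files(["a.mzML", "b.mzML"], {"A": ["a.mzML"]})
    out = tmp_path / "report.tsv"
    linker.write_linkage_report(got, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "run_path\tsample_id\ttier\tstatus"
    assert "a.mzML\tA\tfull_path\taccepted" in lines
    assert "b.mzML\t\t\tunlinked" in lines
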