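"""Z-code mapping, patient completeness and section coverage arithmetic."""
from __future__ import annotations

import random

import pytest

from sdohfr.comparison import (
    CoverageAnnotation,
    load_zcode_map,
    normalize_zcode,
    patient_completeness,
    round_pct,
    section_coverage,
)
from sdohfr.errors import AlignmentError, ConfigError, IntegrityError
from sdohfr.schema import Span


class TestZCodeMap:
    def test_codes_are_dot_insensitive(self):
        zmap = load_zcode_map([("Z60.2", "living condition")])
        assert zmap == {"Z602": "living condition"}
        assert normalize_zcode("z60.2") == "Z602"

    def test_unknown_category_is_config_error(self):
        with pytest.raises(ConfigError):
            load_zcode_map([("Z99.9", "not-a-category")])

    def test_identical_duplicates_collapse_conflicts_raise(self):
        zmap = load_zcode_map([("Z60.2", "living condition"),
                               ("Z602", "living condition")])
        assert len(zmap) == 1
        with pytest.raises(ConfigError):
            load_zcode_map([("Z60.2", "living condition"), ("Z60.2", "housing")])

    def test_non_z_code_rejected(self):
        with pytest.raises(ConfigError):
            load_zcode_map([("I10", "housing")])

    def test_load_from_file(self, tmp_path):
        path = tmp_path / "zmap.csv"
        path.write_text("Z60.2,living condition\nZ59.0,housing\n", encoding="utf-8")
        zmap = load_zcode_map(path)
        assert zmap == {"Z602": "living condition", "Z590": "housing"}


def completeness_fixture(n=1646, n_note=1621, n_z=46, n_both=17):
    """A patient universe realizing the given marginal counts; the first
    ``n_both`` patients are documented (same category) in both sources."""
    notes, zcodes = {}, {}
    for i in range(n):
        pid = f"p{i:04d}"
        notes[pid] = ["living condition"] if i < n_note else []
        zcodes[pid] = ["Z60.2"] if i < n_both else []
        if n_both <= i < n_z:
            # structured-only patients: housing Z-code, no note annotation overlap
            zcodes[pid] = ["Z59.0"]
            notes[pid] = ["tobacco"] if i < n_note else []
    return notes, zcodes


class TestPatientCompleteness:
    def test_reference_counts_give_reference_percentages(self):
        notes, zcodes = completeness_fixture()
        report = patient_completeness(notes, zcodes)
        assert report.n_patients == 1646
        assert report.n_with_note_sdoh == 1621
        assert report.pct_note == 98.5
        assert report.n_with_zcode_sdoh == 46
        assert report.pct_zcode == 2.8
        assert report.n_overlap == 17

    def test_nobody_documented(self):
        notes = {"a": [], "b": []}
        zcodes = {"a": [], "b": []}
        report = patient_completeness(notes, zcodes)
        assert (report.n_with_note_sdoh, report.n_with_zcode_sdoh) == (0, 0)
        assert report.pct_note == report.pct_zcode == 0.0

    def test_overlap_requires_category_intersection(self):
        notes = {"a": ["tobacco"]}
        zcodes = {"a": ["Z60.2"]}  # maps to living condition
        assert patient_completeness(notes, zcodes).n_overlap == 0
        notes = {"a": ["living condition"]}
        assert patient_completeness(notes, zcodes).n_overlap == 1

    def test_invariant_to_order_and_duplicate_codes(self):
        notes, zcodes = completeness_fixture(n=50, n_note=30, n_z=10, n_both=5)
        base = patient_completeness(notes, zcodes)
        shuffled_ids = list(notes)
        random.Random(1).shuffle(shuffled_ids)
        notes2 = {pid: notes[pid] for pid in shuffled_ids}
        zcodes2 = {pid: zcodes[pid] * 3 for pid in shuffled_ids}
        assert patient_completeness(notes2, zcodes2) == base

    def test_empty_universe_is_error(self):
        with pytest.raises(AlignmentError):
            patient_completeness({}, {})

    def test_different_universes_are_error(self):
        with pytest.raises(AlignmentError):
            patient_completeness({"a": []}, {"b": []})


def coverage_fixture():
    """665 annotations: 461 inside; 87 in section-less documents; 117
    outside-section in a sectioned document, 81 of them category-redundant."""
    doc_ids = ["with-sec", "no-sec"]
    sections = {"with-sec": [Span(0, 10_000)]}
    anns = []
    anns += [CoverageAnnotation("with-sec", Span(i * 10, i * 10 + 5), "tobacco")
             for i in range(461)]  # inside
    anns += [CoverageAnnotation("with-sec", Span(20_000 + i * 10, 20_000 + i * 10 + 5),
                                "tobacco") for i in range(81)]  # outside, redundant
    anns += [CoverageAnnotation("with-sec", Span(40_000 + i * 10, 40_000 + i * 10 + 5),
                                "education") for i in range(36)]  # outside, unique
    anns += [CoverageAnnotation("no-sec", Span(i * 10, i * 10 + 5), "alcohol")
             for i in range(87)]
    return doc_ids, sections, anns


class TestSectionCoverage:
    def test_reference_fixture_reproduces_reference_numbers(self):
        report = section_coverage(*coverage_fixture())
        assert report.total == 665
        assert report.inside == 461
        assert report.pct_inside == 69.3
        assert report.outside == 204
        assert report.pct_outside == 30.7
        assert report.outside_no_section == 87
        assert report.outside_redundant == 81
        assert report.missed_unique == 123
        assert report.pct_missed_unique == 18.5

    def test_zero_annotations(self):
        report = section_coverage(["d"], {}, [])
        assert report.total == 0
        assert report.pct_inside == report.pct_missed_unique == 0.0

    def test_straddling_annotation_counts_as_outside(self):
        report = section_coverage(
            ["d"], {"d": [Span(0, 10)]},
            [CoverageAnnotation("d", Span(5, 15), "tobacco")])
        assert report.inside == 0 and report.outside == 1

    def test_unknown_doc_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            section_coverage(["d"], {}, [CoverageAnnotation("x", Span(0, 1), "tobacco")])

    def test_widening_section_never_increases_missed_unique(self):
        doc_ids, sections, anns = coverage_fixture()
        base = section_coverage(doc_ids, sections, anns)
        widened = {"with-sec": [Span(0, 25_000)]}  # swallows the redundant block
        wide = section_coverage(doc_ids, widened, anns)
        assert wide.missed_unique <= base.missed_unique
        assert wide.inside >= base.inside


class TestRounding:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(1621, 1646, 98.5), (46, 1646, 2.8), (461, 665, 69.3),
         (204, 665, 30.7), (123, 665, 18.5), (1, 800, 0.1), (1, 1600, 0.1)],
    )
    def test_half_up_to_one_decimal(self, count, total, expected):
        assert round_pct(count, total) == expected
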