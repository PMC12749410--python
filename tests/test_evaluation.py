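"""Two-level slot-filling evaluation: findings, matching, macro aggregation."""
from __future__ import annotations

import random

import pytest

from sdohfr.errors import AlignmentError
from sdohfr.evaluation import (
    level1_findings,
    match_spans,
    score_level1,
    score_level2,
)
from sdohfr.schema import Span

from conftest import brute_force_max_matching, make_doc, perturb_doc


def tobacco_amount_doc(trig_end=9, doc_id="d"):
    # "Tabagisme à 17" with Amount "17" at (12, 14)
    text = "Tabagisme à 17"
    return make_doc(
        doc_id, text,
        [("T1", "Tobacco", 0, trig_end),
         ("T2", "StatusTime", 0, trig_end),
         ("T3", "Amount", 12, 14)],
        [("Status", "T1", "T2"), ("Amount", "T1", "T3")],
        [("T2", "current")],
    )


class TestLevel1Findings:
    def test_category_label_and_substance_composite(self):
        text = "Vit seul. Tabac sevré."
        doc = make_doc(
            "d", text,
            [("T1", "Living_Alone", 0, 8), ("T2", "Tobacco", 10, 15),
             ("T3", "StatusTime", 16, 21)],
            [("Status", "T2", "T3")], [("T3", "past")],
        )
        assert level1_findings(doc) == {"Living_Alone", "Tobacco_StatusTime:past"}

    def test_span_only_labels_excluded(self):
        doc = make_doc("d", "Soudeur", [("T1", "Job", 0, 7)])
        assert level1_findings(doc) == set()

    def test_empty_document(self):
        assert level1_findings(make_doc("d", "Rien.", [])) == set()

    def test_substance_without_status_warns_and_skips(self):
        doc = make_doc("d", "Tabac", [("T1", "Tobacco", 0, 5)])
        with pytest.warns(UserWarning):
            assert level1_findings(doc) == set()


class TestScoreLevel1:
    def test_perfect_prediction_scores_one(self, synth_corpus):
        report = score_level1(synth_corpus, synth_corpus)
        assert report.overall.precision == report.overall.recall == report.overall.f1 == 1.0

    def test_half_recovered_labels_give_macro_half(self):
        text = "Vit seul. Mariée."
        gold = make_doc("g", text, [("T1", "Living_Alone", 0, 8),
                                    ("T2", "MaritalStatus_InRelationship", 10, 16)])
        pred = make_doc("g", text, [("T1", "Living_Alone", 0, 8)])
        report = score_level1([gold], [pred])
        assert report.overall.f1 == pytest.approx(0.5)
        assert report.counts["Living_Alone"].tp == 1
        assert report.counts["MaritalStatus_InRelationship"].fn == 1

    def test_empty_predictions_give_zero_recall(self):
        gold = make_doc("g", "Vit seul.", [("T1", "Living_Alone", 0, 8)])
        pred = make_doc("g", "Vit seul.", [])
        report = score_level1([gold], [pred])
        assert report.overall.recall == 0.0

    def test_doc_id_mismatch_is_alignment_error(self):
        a = make_doc("a", "x.", [])
        b = make_doc("b", "x.", [])
        with pytest.raises(AlignmentError):
            score_level1([a], [b])


class TestMatchSpans:
    def test_exact_match(self):
        assert match_spans([Span(0, 9)], [Span(0, 9)], "exact") == [(0, 0)]

    def test_overlap_matches_where_exact_does_not(self):
        gold, pred = [Span(0, 15)], [Span(0, 9)]
        assert match_spans(gold, pred, "overlap") == [(0, 0)]
        assert match_spans(gold, pred, "exact") == []

    def test_greedy_equals_maximum_matching_on_small_instances(self):
        rng = random.Random(5)
        for criterion in ("exact", "overlap"):
            for _ in range(300):
                gold = [Span(s, s + rng.randint(1, 5))
                        for s in (rng.randint(0, 30) for _ in range(rng.randint(0, 6)))]
                pred = [Span(s, s + rng.randint(1, 5))
                        for s in (rng.randint(0, 30) for _ in range(rng.randint(0, 6)))]

                def compatible(g, p):
                    if criterion == "exact":
                        return (g.start, g.end) == (p.start, p.end)
                    return g.overlaps(p)

                greedy = len(match_spans(gold, pred, criterion))
                assert greedy == brute_force_max_matching(gold, pred, compatible)


class TestScoreLevel2:
    def test_perfect_prediction_scores_one_under_both_criteria(self, synth_corpus):
        for criterion in ("exact", "overlap"):
            report = score_level2(synth_corpus, synth_corpus, criterion)
            assert report.overall.f1 == 1.0
            for c in report.counts.values():
                if c.active:
                    assert c.f1 == 1.0

    def test_hand_traced_two_stage_example(self):
        gold = tobacco_amount_doc(trig_end=9)
        pred = tobacco_amount_doc(trig_end=5)  # trigger boundary differs
        exact = score_level2([gold], [pred], "exact")
        overlap = score_level2([gold], [pred], "overlap")
        # exact: trigger unmatched, so the identical Amount becomes fp+fn
        assert exact.counts["Tobacco"].f1 == 0.0
        assert exact.counts["Tobacco/Amount"].tp == 0
        assert exact.counts["Tobacco/Amount"].fp == 1
        assert exact.counts["Tobacco/Amount"].fn == 1
        # overlap: trigger matched, both slots recovered
        assert overlap.counts["Tobacco"].f1 == 1.0
        assert overlap.counts["Tobacco/Amount"].f1 == 1.0
        assert overlap.counts["Tobacco/Status"].f1 == 1.0

    def test_status_value_must_match(self):
        gold = tobacco_amount_doc()
        pred_doc = tobacco_amount_doc()
        pred = make_doc(
            "d", pred_doc.text,
            [("T1", "Tobacco", 0, 9), ("T2", "StatusTime", 0, 9), ("T3", "Amount", 12, 14)],
            [("Status", "T1", "T2"), ("Amount", "T1", "T3")],
            [("T2", "past")],  # gold says current
        )
        report = score_level2([gold], [pred], "exact")
        assert report.counts["Tobacco/Status"].tp == 0
        assert report.counts["Tobacco/Amount"].tp == 1

    def test_overlap_never_below_exact_per_key(self, synth_corpus):
        rng = random.Random(13)
        preds = [perturb_doc(d, rng) for d in synth_corpus]
        exact = score_level2(synth_corpus, preds, "exact")
        overlap = score_level2(synth_corpus, preds, "overlap")
        for key, c in exact.counts.items():
            if c.active or overlap.counts[key].active:
                assert overlap.counts[key].f1 >= c.f1 - 1e-12, key

    def test_spurious_event_never_raises_recall(self, synth_corpus):
        gold = synth_corpus[:5]
        base = score_level2(gold, gold, "exact")
        spoiled = []
        for d in gold:
            extra = make_doc(
                d.doc_id, d.text + " Originaire du Maroc.",
                [("X1", "Ethnicity", len(d.text) + 1, len(d.text) + 20)],
            )
            spoiled.append(make_doc(
                d.doc_id, extra.text,
                [(e.id, e.label, e.span.start, e.span.end) for e in d.entities]
                + [("X1", "Ethnicity", len(d.text) + 1, len(d.text) + 20)],
                [(r.type, r.head_id, r.arg_id) for r in d.relations],
                [(a.entity_id, a.value) for a in d.attributes],
            ))
        gold_ext = [make_doc(d.doc_id, s.text,
                             [(e.id, e.label, e.span.start, e.span.end) for e in d.entities],
                             [(r.type, r.head_id, r.arg_id) for r in d.relations],
                             [(a.entity_id, a.value) for a in d.attributes])
                    for d, s in zip(gold, spoiled)]
        spoiled_report = score_level2(gold_ext, spoiled, "exact")
        for key, c in spoiled_report.counts.items():
            if c.active and base.counts.get(key, c).active:
                assert c.recall <= base.counts[key].recall + 1e-12

    def test_macro_is_mean_of_per_key_scores(self, synth_corpus):
        rng = random.Random(3)
        preds = [perturb_doc(d, rng) for d in synth_corpus[:10]]
        report = score_level2(synth_corpus[:10], preds, "overlap")
        active = [c for c in report.counts.values() if c.active]
        assert report.overall.f1 == pytest.approx(
            sum(c.f1 for c in active) / len(active), abs=1e-12)
        for cat, macro in report.per_category.items():
            keys = [k for k, c in report.counts.items()
                    if c.active and _cat(k) == cat]
            assert macro.f1 == pytest.approx(
                sum(report.counts[k].f1 for k in keys) / len(keys), abs=1e-12)


def _cat(key: str) -> str:
    from sdohfr.schema import entity_category

    return entity_category(key.split("/", 1)[0].split("_StatusTime:", 1)[0])
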