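"""Pairwise inter-annotator agreement (IAA) F-measures.

Counts are micro-pooled over documents.  An entity match requires an
identical label and identical span; a relation match requires the same
relation type, identical head (label + span) and identical argument
(label + span), with Status relations additionally requiring an equal
status value.  F = 2tp / (2tp + fp + fn), which is symmetric under
swapping the two annotators.  Two empty annotation sets carry no evidence
of disagreement and score 1.0, flagged as such in reports.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .errors import AlignmentError
from .schema import AnnotatedDocument


def _aligned(docs_a: Sequence[AnnotatedDocument], docs_b: Sequence[AnnotatedDocument]):
    amap = {d.doc_id: d for d in docs_a}
    bmap = {d.doc_id: d for d in docs_b}
    if set(amap) != set(bmap):
        raise AlignmentError("annotator document sets differ by doc_id")
    return [(amap[i], bmap[i]) for i in sorted(amap)]


def _entity_items(doc: AnnotatedDocument) -> Counter:
    return Counter((e.label, e.span.start, e.span.end) for e in doc.entities)


def _relation_items(doc: AnnotatedDocument) -> Counter:
    emap = doc.entity_map()
    items: Counter = Counter()
    for r in doc.relations:
        head = emap.get(r.head_id)
        arg = emap.get(r.arg_id)
        if head is None or arg is None:
            continue
        value = doc.status_value(arg.id) if r.type == "Status" else None
        items[(r.type,
               head.label, head.span.start, head.span.end,
               arg.label, arg.span.start, arg.span.end,
               value)] += 1
    return items


def _micro_f(pairs, item_fn) -> tuple[float, bool]:
    tp = fp = fn = 0
    for da, db in pairs:
        a = item_fn(da)
        b = item_fn(db)
        inter = a & b
        tp += sum(inter.values())
        fp += sum((a - b).values())
        fn += sum((b - a).values())
    if tp == fp == fn == 0:
        return 1.0, True
    return 2 * tp / (2 * tp + fp + fn), False


def entity_agreement(
    docs_a: Sequence[AnnotatedDocument], docs_b: Sequence[AnnotatedDocument]
) -> float:
    """Micro-pooled entity F-measure between two annotators."""
    f, _ = _micro_f(_aligned(docs_a, docs_b), _entity_items)
    return f


def relation_agreement(
    docs_a: Sequence[AnnotatedDocument], docs_b: Sequence[AnnotatedDocument]
) -> float:
    """Micro-pooled relation F-measure between two annotators."""
    f, _ = _micro_f(_aligned(docs_a, docs_b), _relation_items)
    return f


@dataclass(frozen=True)
class PairAgreement:
    annotator_a: str
    annotator_b: str
    entity_f: float
    relation_f: float
    entities_empty: bool
    relations_empty: bool


@dataclass(frozen=True)
class AgreementReport:
    """Agreement per annotator pair with an unweighted mean over pairs."""

    pairs: tuple[PairAgreement, ...]
    mean_entity_f: float
    mean_relation_f: float

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"annotators": [p.annotator_a, p.annotator_b],
                 "entity_f": p.entity_f, "relation_f": p.relation_f,
                 "entities_empty": p.entities_empty,
                 "relations_empty": p.relations_empty}
                for p in self.pairs
            ],
            "mean_entity_f": self.mean_entity_f,
            "mean_relation_f": self.mean_relation_f,
        }


def agreement_report(
    annotations: Mapping[str, Sequence[AnnotatedDocument]]
) -> AgreementReport:
    """Pairwise agreement over all unordered annotator pairs."""
    names = sorted(annotations)
    if len(names) < 2:
        raise AlignmentError("agreement needs at least two annotators")
    pairs = []
    for a, b in combinations(names, 2):
        aligned = _aligned(annotations[a], annotations[b])
        ef, e_empty = _micro_f(aligned, _entity_items)
        rf, r_empty = _micro_f(aligned, _relation_items)
        pairs.append(PairAgreement(a, b, ef, rf, e_empty, r_empty))
    return AgreementReport(
        tuple(pairs),
        sum(p.entity_f for p in pairs) / len(pairs),
        sum(p.relation_f for p in pairs) / len(pairs),
    )
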