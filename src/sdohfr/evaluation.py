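"""Two-level scoring of predicted vs gold SDoH documents.

**Level 1** measures per-document presence of *labeled* findings: the 17
category-valued labels (e.g. ``Housing_No``) plus, for substances, a
composite of trigger and status — ``Tobacco_StatusTime:current`` — giving
26 possible finding labels.  Span-only labels (Job, Last_job, Income,
Education, Ethnicity) do not participate at this level.

**Level 2** scores extraction as a slot-filling task over evaluation keys:
one key per SDoH trigger label and one per legal (label, relation) pair.
Scoring is two-stage, in the style of the n2c2 substance-abuse shared-task
scorers: triggers are matched first (greedy 1-to-1 in ascending span
order), then, within each matched trigger pair, argument spans are matched
per relation type; Status arguments additionally require an equal status
value.  Arguments hanging off unmatched triggers count as false positives
(prediction side) or false negatives (gold side).

Two span-equivalence criteria are supported: ``exact`` (identical offsets)
and ``overlap`` (at least one shared character) — the latter treats
alternative-but-equivalent span choices for the same mention as equal.

Macro aggregation is the unweighted mean of per-key precision / recall /
F1 over keys with any activity (tp+fp+fn > 0); inactive keys are excluded.
Per-category scores average the keys whose head label belongs to the
category.  Zero-denominator convention: a precision (or recall) whose
denominator is 0 while the other count is positive is 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import AlignmentError
from .schema import (
    CATEGORY_VALUED_LABELS,
    SDOH_LABELS,
    STATUS_VALUES,
    SUBSTANCE_LABELS,
    AnnotatedDocument,
    Span,
    entity_category,
    legal_relation_types,
)
from .serializer import events_of

Criterion = Literal["exact", "overlap"]

#: The 26 possible level-1 finding labels.
LEVEL1_LABELS: tuple[str, ...] = CATEGORY_VALUED_LABELS + tuple(
    f"{sub}_StatusTime:{val}" for sub in SUBSTANCE_LABELS for val in STATUS_VALUES
)


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @property
    def active(self) -> bool:
        return (self.tp + self.fp + self.fn) > 0


@dataclass(frozen=True)
class MacroScores:
    precision: float
    recall: float
    f1: float
    n_keys: int


@dataclass
class EvalReport:
    """Per-key counts with per-category and overall macro averages."""

    level: int
    criterion: str | None
    counts: dict[str, EvalCounts]
    per_category: dict[str, MacroScores] = field(default_factory=dict)
    overall: MacroScores = MacroScores(0.0, 0.0, 0.0, 0)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "criterion": self.criterion,
            "keys": {
                k: {"tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "precision": c.precision, "recall": c.recall, "f1": c.f1}
                for k, c in sorted(self.counts.items()) if c.active
            },
            "per_category": {
                cat: {"precision": m.precision, "recall": m.recall,
                      "f1": m.f1, "n_keys": m.n_keys}
                for cat, m in sorted(self.per_category.items())
            },
            "overall": {"precision": self.overall.precision, "recall": self.overall.recall,
                        "f1": self.overall.f1, "n_keys": self.overall.n_keys},
        }


def _key_category(key: str) -> str:
    label = key.split("/", 1)[0].split("_StatusTime:", 1)[0]
    return entity_category(label)


def _finalize(level: int, criterion: str | None, counts: dict[str, EvalCounts]) -> EvalReport:
    active = {k: c for k, c in counts.items() if c.active}

    def macro(keys: Iterable[str]) -> MacroScores:
        keys = list(keys)
        if not keys:
            return MacroScores(0.0, 0.0, 0.0, 0)
        p = sum(active[k].precision for k in keys) / len(keys)
        r = sum(active[k].recall for k in keys) / len(keys)
        f = sum(active[k].f1 for k in keys) / len(keys)
        return MacroScores(p, r, f, len(keys))

    by_cat: dict[str, list[str]] = {}
    for k in active:
        by_cat.setdefault(_key_category(k), []).append(k)
    per_category = {cat: macro(keys) for cat, keys in by_cat.items()}
    return EvalReport(level, criterion, counts, per_category, macro(active.keys()))


def _aligned(gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]):
    gmap = {d.doc_id: d for d in gold}
    pmap = {d.doc_id: d for d in pred}
    if set(gmap) != set(pmap):
        only_g = sorted(set(gmap) - set(pmap))[:3]
        only_p = sorted(set(pmap) - set(gmap))[:3]
        raise AlignmentError(
            f"corpora are not aligned by doc_id (gold-only {only_g}, pred-only {only_p})")
    return [(gmap[i], pmap[i]) for i in sorted(gmap)]


# --------------------------------------------------------------------------- #
# Level 1


def level1_findings(doc: AnnotatedDocument) -> set[str]:
    """The document's labeled findings (set semantics: duplicates collapse).

    Category-valued mentions contribute their label; substance triggers
    with a Status relation contribute ``<label>_StatusTime:<value>``.  A
    substance trigger without a Status relation is skipped with a warning.
    """
    findings: set[str] = set()
    emap = doc.entity_map()
    for e in doc.entities:
        if e.label in CATEGORY_VALUED_LABELS:
            findings.add(e.label)
        elif e.label in SUBSTANCE_LABELS:
            value = None
            for rel in doc.relations_from(e.id):
                if rel.type == "Status":
                    arg = emap.get(rel.arg_id)
                    if arg is not None:
                        value = doc.status_value(arg.id)
            if value is None:
                warnings.warn(
                    f"{doc.doc_id}: {e.label} trigger {e.id} has no Status value; "
                    f"finding skipped", stacklevel=2)
                continue
            findings.add(f"{e.label}_StatusTime:{value}")
    return findings


def score_level1(
    gold_corpus: Sequence[AnnotatedDocument], pred_corpus: Sequence[AnnotatedDocument]
) -> EvalReport:
    """Document-level presence scoring of labeled findings.

    Per finding label: tp = documents where gold and prediction both
    contain it, fp = prediction only, fn = gold only; macro over labels
    with any activity.
    """
    counts = {lab: EvalCounts() for lab in LEVEL1_LABELS}
    for gdoc, pdoc in _aligned(gold_corpus, pred_corpus):
        g = level1_findings(gdoc)
        p = level1_findings(pdoc)
        for lab in g & p:
            counts[lab].tp += 1
        for lab in p - g:
            counts[lab].fp += 1
        for lab in g - p:
            counts[lab].fn += 1
    return _finalize(1, None, counts)


# --------------------------------------------------------------------------- #
# Span matching


def _criterion_ok(a: Span, b: Span, criterion: Criterion) -> bool:
    if criterion == "exact":
        return a.start == b.start and a.end == b.end
    return a.overlaps(b)


def _match_items(
    gold: list[tuple[Span, object]],
    pred: list[tuple[Span, object]],
    criterion: Criterion,
) -> list[tuple[int, int]]:
    """Greedy 1-to-1 matching; payloads (e.g. status values) must be equal.

    Spans are processed in ascending end-then-start order on both sides —
    the earliest-ending compatible gold span is taken first.  For interval
    overlap (and a fortiori exact equality) this greedy is a maximum
    matching, so the scorer never penalizes a prediction for matching
    order artifacts; the test suite checks this against an exhaustive
    oracle.
    """
    g_order = sorted(range(len(gold)), key=lambda i: (gold[i][0].end, gold[i][0].start, i))
    p_order = sorted(range(len(pred)), key=lambda i: (pred[i][0].end, pred[i][0].start, i))
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi in p_order:
        for gi in g_order:
            if gi in taken:
                continue
            if gold[gi][1] != pred[pi][1]:
                continue
            if _criterion_ok(gold[gi][0], pred[pi][0], criterion):
                taken.add(gi)
                pairs.append((gi, pi))
                break
    return pairs


def match_spans(
    gold_spans: Sequence[Span], pred_spans: Sequence[Span], criterion: Criterion
) -> list[tuple[int, int]]:
    """Greedy 1-to-1 span matching, equivalent to a maximum matching.

    Each predicted span (ascending end order) pairs with the first
    unmatched gold span satisfying the criterion; returns
    (gold_index, pred_index) pairs.
    """
    return _match_items([(s, None) for s in gold_spans],
                        [(s, None) for s in pred_spans], criterion)


# --------------------------------------------------------------------------- #
# Level 2


def _pair_key(label: str, rel_type: str) -> str:
    return f"{label}/{rel_type}"


def score_level2(
    gold_corpus: Sequence[AnnotatedDocument],
    pred_corpus: Sequence[AnnotatedDocument],
    criterion: Criterion,
) -> EvalReport:
    """Slot-filling evaluation over trigger keys and (label, relation) keys."""
    if criterion not in ("exact", "overlap"):
        raise ValueError(f"criterion must be 'exact' or 'overlap', got {criterion!r}")
    counts: dict[str, EvalCounts] = {lab: EvalCounts() for lab in SDOH_LABELS}
    for lab in SDOH_LABELS:
        for rel in legal_relation_types(lab):
            counts[_pair_key(lab, rel)] = EvalCounts()

    for gdoc, pdoc in _aligned(gold_corpus, pred_corpus):
        gev = events_of(gdoc)
        pev = events_of(pdoc)
        for lab in SDOH_LABELS:
            g_trigs = [e for e in gev if e.trigger_label == lab]
            p_trigs = [e for e in pev if e.trigger_label == lab]
            if not g_trigs and not p_trigs:
                continue
            pairs = _match_items([(e.trigger_span, None) for e in g_trigs],
                                 [(e.trigger_span, None) for e in p_trigs], criterion)
            counts[lab].tp += len(pairs)
            counts[lab].fp += len(p_trigs) - len(pairs)
            counts[lab].fn += len(g_trigs) - len(pairs)

            matched_g = {gi for gi, _ in pairs}
            matched_p = {pi for _, pi in pairs}
            for gi, pi in pairs:
                for rel in legal_relation_types(lab):
                    g_args = [(a.span, a.status_value) for a in g_trigs[gi].args
                              if a.rel_type == rel]
                    p_args = [(a.span, a.status_value) for a in p_trigs[pi].args
                              if a.rel_type == rel]
                    if not g_args and not p_args:
                        continue
                    apairs = _match_items(g_args, p_args, criterion)
                    key = _pair_key(lab, rel)
                    counts[key].tp += len(apairs)
                    counts[key].fp += len(p_args) - len(apairs)
                    counts[key].fn += len(g_args) - len(apairs)
            for gi, ev in enumerate(g_trigs):
                if gi not in matched_g:
                    for a in ev.args:
                        counts[_pair_key(lab, a.rel_type)].fn += 1
            for pi, ev in enumerate(p_trigs):
                if pi not in matched_p:
                    for a in ev.args:
                        counts[_pair_key(lab, a.rel_type)].fp += 1

    return _finalize(2, criterion, counts)
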