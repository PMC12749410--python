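"""Recover character offsets for parsed, ungrounded SDoH events.

Generated event strings carry surface text but no offsets.  Grounding maps
them back onto the source text with greedy disambiguation rules:

* **Triggers** (processed in sequence order) take the leftmost occurrence
  of their text whose span has not already been consumed by a previously
  grounded trigger; two distinct triggers therefore never share a span.
* **Arguments** take the occurrence of their text whose midpoint is nearest
  (absolute character distance) to the grounded trigger's midpoint, ties
  resolved leftmost.  Argument spans may be reused across events —
  quantities like "20" legitimately repeat.

Matching escalates exact → case-insensitive → diacritic-folded (the last
level recovers accents corrupted by an English-centric tokenizer, e.g.
"cocane" for "cocaïne"); fuzzy levels are logged.  Ungroundable items are
dropped with a diagnostic rather than raising; a substance event whose
Status argument cannot be grounded is dropped entirely so that the output
document always passes schema validation.  The rules are deliberately
greedy, not a global optimal assignment.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._text import nfc, occurrences
from .schema import (
    SUBSTANCE_LABELS,
    AnnotatedDocument,
    AttributeAssignment,
    EntityMention,
    RelationMention,
    Span,
)
from .serializer import SDoHEvent

#: Entity label carried by the argument of each relation type.
ARG_LABEL_FOR_RELATION: dict[str, str] = {
    "Status": "StatusTime",
    "History": "History",
    "Duration": "Duration",
    "Amount": "Amount",
    "Frequency": "Frequency",
    "Type": "Type",
}

_FUZZY_NAMES = {1: "case-insensitive", 2: "diacritic-folded"}


@dataclass(frozen=True)
class GroundingDiagnostic:
    kind: str  # "no-match" | "fuzzy-match" | "ambiguous-resolved" | "dropped"
    detail: str


def ground_events(
    events: list[SDoHEvent], text: str, doc_id: str = "doc"
) -> tuple[AnnotatedDocument, list[GroundingDiagnostic]]:
    """Assign spans to events in ``text`` and build an annotated document."""
    text = nfc(text)
    diags: list[GroundingDiagnostic] = []
    consumed: set[tuple[int, int]] = set()
    grounded: list[tuple[SDoHEvent, Span, list[tuple[int, Span]]]] = []

    for ev in events:
        spans, level = occurrences(ev.trigger_text, text)
        candidates = [s for s in spans if (s.start, s.end) not in consumed]
        if not spans:
            diags.append(GroundingDiagnostic(
                "no-match", f"trigger {ev.trigger_label} [{ev.trigger_text}] not found"))
            diags.append(GroundingDiagnostic(
                "dropped", f"event {ev.trigger_label} [{ev.trigger_text}]"))
            continue
        if not candidates:
            diags.append(GroundingDiagnostic(
                "dropped",
                f"event {ev.trigger_label} [{ev.trigger_text}]: all occurrences consumed"))
            continue
        if level:
            diags.append(GroundingDiagnostic(
                "fuzzy-match",
                f"trigger [{ev.trigger_text}] matched {_FUZZY_NAMES[level]}"))
        if len(candidates) > 1:
            diags.append(GroundingDiagnostic(
                "ambiguous-resolved",
                f"trigger [{ev.trigger_text}]: {len(candidates)} occurrences, "
                f"leftmost unconsumed taken"))
        trig_span = candidates[0]
        consumed.add((trig_span.start, trig_span.end))

        arg_spans: list[tuple[int, Span]] = []
        for i, arg in enumerate(ev.args):
            a_spans, a_level = occurrences(arg.text, text)
            if not a_spans:
                diags.append(GroundingDiagnostic(
                    "no-match", f"argument {arg.rel_type} [{arg.text}] not found"))
                diags.append(GroundingDiagnostic(
                    "dropped", f"argument {arg.rel_type} [{arg.text}]"))
                continue
            if a_level:
                diags.append(GroundingDiagnostic(
                    "fuzzy-match",
                    f"argument [{arg.text}] matched {_FUZZY_NAMES[a_level]}"))
            if len(a_spans) > 1:
                diags.append(GroundingDiagnostic(
                    "ambiguous-resolved",
                    f"argument [{arg.text}]: {len(a_spans)} occurrences, nearest taken"))
            best = min(a_spans, key=lambda s: (abs(s.midpoint - trig_span.midpoint), s.start))
            arg_spans.append((i, best))

        if ev.trigger_label in SUBSTANCE_LABELS and not any(
            ev.args[i].rel_type == "Status" for i, _ in arg_spans
        ):
            diags.append(GroundingDiagnostic(
                "dropped",
                f"event {ev.trigger_label} [{ev.trigger_text}]: no groundable Status"))
            consumed.discard((trig_span.start, trig_span.end))
            continue
        grounded.append((ev, trig_span, arg_spans))

    return _build_document(grounded, text, doc_id), diags


def _build_document(
    grounded: list[tuple[SDoHEvent, Span, list[tuple[int, Span]]]],
    text: str,
    doc_id: str,
) -> AnnotatedDocument:
    entities: list[EntityMention] = []
    attributes: list[AttributeAssignment] = []
    relations: list[RelationMention] = []
    # reuse an argument entity when label, span and (for StatusTime) value agree
    arg_ids: dict[tuple[str, int, int, str | None], str] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter}"

    for ev, trig_span, arg_spans in grounded:
        tid = new_id()
        entities.append(EntityMention(tid, ev.trigger_label,
                                      trig_span, text[trig_span.start:trig_span.end]))
        for i, span in arg_spans:
            arg = ev.args[i]
            label = ARG_LABEL_FOR_RELATION[arg.rel_type]
            key = (label, span.start, span.end, arg.status_value)
            aid = arg_ids.get(key)
            if aid is None:
                aid = new_id()
                arg_ids[key] = aid
                entities.append(EntityMention(aid, label, span, text[span.start:span.end]))
                if arg.rel_type == "Status":
                    attributes.append(AttributeAssignment(aid, arg.status_value))
            relations.append(RelationMention(arg.rel_type, tid, aid))

    return AnnotatedDocument(doc_id, text, tuple(entities), tuple(attributes), tuple(relations))
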