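"""Linearize SDoH events to the seq2seq target string, and parse it back.

A document's events are rendered as a single left-to-right string, the
format a text-to-structure model is trained to emit::

    Living_Alone [Vit seul] ; Tobacco [Tabac] Status=past [sevré] History [il y a 8 ans]

Grammar (the single normative dialect of this toolkit):

* events are joined by ``" ; "``;
* an event is ``LABEL " [" trigger_text "]"`` followed by zero or more args;
* an arg is ``REL_TYPE " [" arg_text "]"``, with ``"=" status_value`` after
  the relation type for Status args;
* the characters ``[ ] ; \\`` inside texts are escaped with a backslash;
* events are ordered by trigger start offset (ties: label lexicographic)
  and args within an event by argument start offset.

Text is kept verbatim (no ASCII folding): accented surfaces such as
"cocaïne" survive serialization; fuzzy recovery of corrupted accents is the
grounding step's job.  Parsing never raises on model output: malformed
segments are skipped and reported as diagnostics.

Argument mentions that no relation attaches to cannot head an event and are
omitted from the serialization (the generator never produces them).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import SchemaError
from .schema import (
    RELATION_TYPES,
    SDOH_LABELS,
    STATUS_VALUES,
    AnnotatedDocument,
    Span,
    allowed_relation,
    validate_document,
)

_SPECIAL = "\\[];"


def escape(s: str) -> str:
    return "".join("\\" + c if c in _SPECIAL else c for c in s)


def unescape(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append(s[i + 1])
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


@dataclass(frozen=True)
class EventArg:
    """One argument slot of an SDoH event."""

    rel_type: str
    status_value: str | None  # present iff rel_type == "Status"
    text: str
    span: Span | None = None  # absent while ungrounded


@dataclass(frozen=True)
class SDoHEvent:
    """A trigger mention with its attached argument slots."""

    trigger_label: str
    trigger_text: str
    trigger_span: Span | None = None
    args: tuple[EventArg, ...] = ()

    def ungrounded(self) -> "SDoHEvent":
        """The same event with all spans stripped (for round-trip comparison)."""
        return SDoHEvent(
            self.trigger_label,
            self.trigger_text,
            None,
            tuple(EventArg(a.rel_type, a.status_value, a.text, None) for a in self.args),
        )


@dataclass(frozen=True)
class Diagnostic:
    kind: str  # "malformed-segment" | "dropped-argument"
    detail: str


def events_of(doc: AnnotatedDocument) -> list[SDoHEvent]:
    """The document's grounded events, in serialization order.

    Every SDoH-labeled mention heads exactly one event (argument-free when
    no relation attaches to it).  Argument mentions appear only inside the
    events of their heads.
    """
    emap = doc.entity_map()
    events = []
    triggers = sorted(doc.sdoh_entities(), key=lambda e: (e.span.start, e.label, e.span.end))
    for trig in triggers:
        args = []
        for rel in doc.relations_from(trig.id):
            arg_ent = emap.get(rel.arg_id)
            if arg_ent is None:
                continue
            value = doc.status_value(arg_ent.id) if rel.type == "Status" else None
            args.append(EventArg(rel.type, value, arg_ent.surface, arg_ent.span))
        args.sort(key=lambda a: (a.span.start, a.rel_type))  # type: ignore[union-attr]
        events.append(SDoHEvent(trig.label, trig.surface, trig.span, tuple(args)))
    return events


def serialize_events(events: list[SDoHEvent]) -> str:
    """Render events (grounded or not) in their given order."""
    parts = []
    for ev in events:
        bits = [f"{ev.trigger_label} [{escape(ev.trigger_text)}]"]
        for a in ev.args:
            head = a.rel_type
            if a.rel_type == "Status" and a.status_value is not None:
                head += f"={a.status_value}"
            bits.append(f"{head} [{escape(a.text)}]")
        parts.append(" ".join(bits))
    return " ; ".join(parts)


def serialize_document(doc: AnnotatedDocument) -> str:
    """The document's linearized event sequence (deterministic).

    Refuses documents that violate the scheme.
    """
    violations = validate_document(doc)
    if violations:
        detail = "; ".join(f"{v.rule}[{v.subject}]" for v in violations[:5])
        raise SchemaError(f"{doc.doc_id}: refusing to serialize invalid document: {detail}")
    return serialize_events(events_of(doc))


# --------------------------------------------------------------------------- #
# Parsing model output (untrusted)

_TOKEN = re.compile(r"([A-Za-z_]+)(?:\s*=\s*([^\s\[\]]+))?\s*\[((?:\\.|[^\\\[\]])*)\]")


def _split_segments(s: str) -> list[str]:
    parts: list[str] = []
    cur: list[str] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            cur.append(s[i:i + 2])
            i += 2
            continue
        if c == ";":
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(c)
        i += 1
    parts.append("".join(cur))
    return parts


def parse_sequence(seq: str) -> tuple[list[SDoHEvent], list[Diagnostic]]:
    """Parse a generated sequence into ungrounded events plus diagnostics.

    Well-formed segments become events with spans absent.  Malformed
    segments (or malformed tails of a segment) are reported as
    ``malformed-segment`` diagnostics; arguments with an unknown status
    value or an illegal (trigger, relation) pairing are dropped with a
    ``dropped-argument`` diagnostic.  Never raises on any input string.
    """
    events: list[SDoHEvent] = []
    diagnostics: list[Diagnostic] = []
    for segment in _split_segments(seq):
        if not segment.strip():
            continue
        pos = 0
        trig_label: str | None = None
        trig_text = ""
        args: list[EventArg] = []
        ok_tail = True
        while pos < len(segment):
            while pos < len(segment) and segment[pos].isspace():
                pos += 1
            if pos >= len(segment):
                break
            m = _TOKEN.match(segment, pos)
            if m is None:
                ok_tail = False
                break
            name, value, raw_text = m.group(1), m.group(2), m.group(3)
            text = unescape(raw_text)
            if trig_label is None:
                if name not in SDOH_LABELS:
                    ok_tail = False
                    break
                if value is not None:
                    ok_tail = False
                    break
                trig_label, trig_text = name, text
            else:
                if name not in RELATION_TYPES:
                    ok_tail = False
                    break
                if name == "Status":
                    if value not in STATUS_VALUES:
                        diagnostics.append(Diagnostic(
                            "dropped-argument",
                            f"unknown status value {value!r} in segment {segment.strip()!r}"))
                        pos = m.end()
                        continue
                elif value is not None:
                    diagnostics.append(Diagnostic(
                        "dropped-argument",
                        f"unexpected value on {name} in segment {segment.strip()!r}"))
                    pos = m.end()
                    continue
                if not allowed_relation(name, trig_label,
                                        "StatusTime" if name == "Status" else name):
                    diagnostics.append(Diagnostic(
                        "dropped-argument",
                        f"illegal pair ({trig_label}, {name}) in segment {segment.strip()!r}"))
                    pos = m.end()
                    continue
                args.append(EventArg(name, value if name == "Status" else None, text))
            pos = m.end()
        if trig_label is not None:
            events.append(SDoHEvent(trig_label, trig_text, None, tuple(args)))
        if not ok_tail:
            diagnostics.append(Diagnostic("malformed-segment", segment.strip()))
    return events, diagnostics
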