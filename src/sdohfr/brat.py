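"""Read and write BRAT standoff annotation (.txt / .ann pairs) for the scheme.

Only T (text-bound entity), A (attribute) and R (relation) records are
supported: the substance-use events in this scheme anchor on a trigger span
plus a Status relation, so BRAT E/N records are never produced.  Offsets are
code points over NFC text.  Discontinuous spans ("start end;start end") are
replaced by their covering envelope with a warning — the scheme does not use
fragments, and the envelope keeps span-based evaluation well defined.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator

from . import _text
from .errors import IntegrityError, SchemaError
from .schema import (
    STATUS_ATTRIBUTE_NAME,
    AnnotatedDocument,
    AttributeAssignment,
    EntityMention,
    RelationMention,
    Span,
    validate_document,
)


def parse_brat(text_content: str, ann_content: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Parse a .txt/.ann pair into a schema-validated document.

    Surfaces in T lines are re-checked against the text at the stated
    offsets; a mismatch raises :class:`IntegrityError` naming the T id.
    Unknown labels raise :class:`SchemaError`.  Unknown attribute names
    other than ``StatusTimeVal`` are dropped with a warning.  Parsing is
    insensitive to the line order of the .ann file.
    """
    text = _text.nfc(text_content)
    entities: list[EntityMention] = []
    attributes: list[AttributeAssignment] = []
    relations: list[RelationMention] = []
    for raw in ann_content.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 2:
                raise IntegrityError(f"{doc_id}: malformed T line: {line!r}")
            head = fields[1]
            given_surface = _text.nfc(fields[2]) if len(fields) > 2 else ""
            label, _, offsets = head.partition(" ")
            frags = []
            for frag in offsets.split(";"):
                parts = frag.split()
                if len(parts) != 2:
                    raise IntegrityError(f"{doc_id}: bad offsets in {tag}: {offsets!r}")
                frags.append((int(parts[0]), int(parts[1])))
            start = min(f[0] for f in frags)
            end = max(f[1] for f in frags)
            if len(frags) > 1:
                warnings.warn(
                    f"{doc_id}: discontinuous span on {tag} replaced by envelope "
                    f"({start}, {end})",
                    stacklevel=2,
                )
            if end > len(text):
                raise IntegrityError(
                    f"{doc_id}: {tag} span ({start}, {end}) exceeds text length {len(text)}"
                )
            surface = text[start:end]
            if len(frags) == 1 and given_surface and given_surface != surface:
                raise IntegrityError(
                    f"{doc_id}: {tag} surface {given_surface!r} does not match text "
                    f"{surface!r} at ({start}, {end})"
                )
            entities.append(EntityMention(tag, label, Span(start, end), surface))
        elif tag.startswith("A"):
            if len(fields) < 2:
                raise IntegrityError(f"{doc_id}: malformed A line: {line!r}")
            parts = fields[1].split()
            if len(parts) != 3:
                raise IntegrityError(f"{doc_id}: malformed A line: {line!r}")
            name, target, value = parts
            if name != STATUS_ATTRIBUTE_NAME:
                warnings.warn(f"{doc_id}: dropping unknown attribute {name!r} on {target}",
                              stacklevel=2)
                continue
            attributes.append(AttributeAssignment(target, value))
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise IntegrityError(f"{doc_id}: malformed R line: {line!r}")
            parts = fields[1].split()
            if len(parts) != 3 or not parts[1].startswith("Arg1:") or not parts[2].startswith("Arg2:"):
                raise IntegrityError(f"{doc_id}: malformed R line: {line!r}")
            relations.append(
                RelationMention(parts[0], parts[1][len("Arg1:"):], parts[2][len("Arg2:"):])
            )
        else:
            warnings.warn(f"{doc_id}: ignoring unsupported standoff line kind {tag!r}",
                          stacklevel=2)
    doc = AnnotatedDocument(doc_id, text, tuple(entities), tuple(attributes), tuple(relations))
    violations = validate_document(doc)
    if violations:
        detail = "; ".join(f"{v.rule}[{v.subject}]" for v in violations[:5])
        raise SchemaError(f"{doc_id}: document violates the scheme: {detail}")
    return doc


def emit_brat(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a valid document to (text_content, ann_content).

    Ids are renumbered densely from 1 in document order (entities by span,
    then attributes, then relations); ``parse_brat(*emit_brat(doc))``
    reproduces the document up to that renumbering.
    """
    violations = validate_document(doc)
    if violations:
        detail = "; ".join(f"{v.rule}[{v.subject}]: {v.message}" for v in violations)
        raise SchemaError(f"{doc.doc_id}: refusing to emit invalid document: {detail}")
    order = sorted(doc.entities, key=lambda e: (e.span.start, e.span.end, e.label, e.id))
    new_id = {e.id: f"T{i}" for i, e in enumerate(order, start=1)}
    lines = [
        f"{new_id[e.id]}\t{e.label} {e.span.start} {e.span.end}\t{e.surface}"
        for e in order
    ]
    attrs = sorted(doc.attributes, key=lambda a: int(new_id[a.entity_id][1:]))
    for i, a in enumerate(attrs, start=1):
        lines.append(f"A{i}\t{STATUS_ATTRIBUTE_NAME} {new_id[a.entity_id]} {a.value}")
    rels = sorted(
        doc.relations,
        key=lambda r: (int(new_id[r.head_id][1:]), int(new_id[r.arg_id][1:]), r.type),
    )
    for i, r in enumerate(rels, start=1):
        lines.append(f"R{i}\t{r.type} Arg1:{new_id[r.head_id]} Arg2:{new_id[r.arg_id]}")
    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.text, ann


# --------------------------------------------------------------------------- #
# Directory-level corpus IO


def read_document(txt_path: str | Path) -> AnnotatedDocument:
    txt_path = Path(txt_path)
    ann_path = txt_path.with_suffix(".ann")
    text = txt_path.read_text(encoding="utf-8")
    ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
    return parse_brat(text, ann, doc_id=txt_path.stem)


def read_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    """All .txt/.ann pairs under a directory, sorted by document id."""
    directory = Path(directory)
    docs = [read_document(p) for p in sorted(directory.glob("*.txt"))]
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for doc in docs:
        text, ann = emit_brat(doc)
        txt_path = directory / f"{doc.doc_id}.txt"
        txt_path.write_text(text, encoding="utf-8")
        txt_path.with_suffix(".ann").write_text(ann, encoding="utf-8")
        written.append(txt_path)
    return written
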