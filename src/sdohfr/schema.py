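"""Annotation scheme for social determinants of health (SDoH) in French clinical notes.

The scheme covers 25 SDoH entity labels grouped into 13 categories (living
condition, marital status, descendants, employment status, job, tobacco,
alcohol, drug, housing, education, physical activity, income,
ethnicity/country of birth) plus 6 argument labels (StatusTime, History,
Duration, Amount, Frequency, Type) that attach to SDoH triggers through
typed relations.  Substance use (tobacco, alcohol, drug) is annotated as an
event: only the trigger span is marked, and the consumption status
(current / past / none) lives on a StatusTime mention linked by a required
``Status`` relation.

This module is the single source of truth for label names, the
label-to-category map, legal relation triples and attribute values, and it
validates whole documents against those rules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import SchemaError

# --------------------------------------------------------------------------- #
# Registry

SDOH_LABELS: tuple[str, ...] = (
    "Living_Alone",
    "Living_WithOthers",
    "MaritalStatus_Single",
    "MaritalStatus_InRelationship",
    "MaritalStatus_Divorced",
    "MaritalStatus_Widowed",
    "Descendants_Yes",
    "Descendants_No",
    "Job",
    "Last_job",
    "Employment_Working",
    "Employment_Unemployed",
    "Employment_Student",
    "Employment_Pensioner",
    "Employment_Other",
    "Alcohol",
    "Tobacco",
    "Drug",
    "Housing_Yes",
    "Housing_No",
    "PhysicalActivity_Yes",
    "PhysicalActivity_No",
    "Income",
    "Education",
    "Ethnicity",
)

ARGUMENT_LABELS: tuple[str, ...] = (
    "StatusTime",
    "History",
    "Duration",
    "Amount",
    "Frequency",
    "Type",
)

ALL_LABELS: tuple[str, ...] = SDOH_LABELS + ARGUMENT_LABELS

RELATION_TYPES: tuple[str, ...] = ("Status", "Amount", "Duration", "Frequency", "History", "Type")

STATUS_VALUES: tuple[str, ...] = ("current", "past", "none")

SUBSTANCE_LABELS: tuple[str, ...] = ("Tobacco", "Alcohol", "Drug")

CATEGORIES: tuple[str, ...] = (
    "living condition",
    "marital status",
    "descendants",
    "employment status",
    "job",
    "tobacco",
    "alcohol",
    "drug",
    "housing",
    "education",
    "physical activity",
    "income",
    "ethnicity/country of birth",
)

CATEGORY_MAP: dict[str, str] = {
    "Living_Alone": "living condition",
    "Living_WithOthers": "living condition",
    "MaritalStatus_Single": "marital status",
    "MaritalStatus_InRelationship": "marital status",
    "MaritalStatus_Divorced": "marital status",
    "MaritalStatus_Widowed": "marital status",
    "Descendants_Yes": "descendants",
    "Descendants_No": "descendants",
    "Employment_Working": "employment status",
    "Employment_Unemployed": "employment status",
    "Employment_Student": "employment status",
    "Employment_Pensioner": "employment status",
    "Employment_Other": "employment status",
    "Job": "job",
    "Last_job": "job",
    "Tobacco": "tobacco",
    "Alcohol": "alcohol",
    "Drug": "drug",
    "Housing_Yes": "housing",
    "Housing_No": "housing",
    "Education": "education",
    "PhysicalActivity_Yes": "physical activity",
    "PhysicalActivity_No": "physical activity",
    "Income": "income",
    "Ethnicity": "ethnicity/country of birth",
}

#: SDoH labels whose mention is a bare text span (no category value carried by
#: the label itself beyond the concept); substances are span-only triggers
#: whose value lives on StatusTime.
SPAN_ONLY_LABELS: tuple[str, ...] = (
    "Job",
    "Last_job",
    "Income",
    "Education",
    "Ethnicity",
    "Alcohol",
    "Tobacco",
    "Drug",
)

#: The 17 labels that already carry their category value (e.g. Housing_No).
CATEGORY_VALUED_LABELS: tuple[str, ...] = tuple(
    lab for lab in SDOH_LABELS if lab not in SPAN_ONLY_LABELS
)

# Legal (relation type, head label, argument label) triples.  History accepts
# any SDoH head; it is expanded below so membership tests are a plain lookup.
_EXPLICIT_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("Status", "Tobacco", "StatusTime"),
    ("Status", "Alcohol", "StatusTime"),
    ("Status", "Drug", "StatusTime"),
    ("Amount", "Descendants_Yes", "Amount"),
    ("Amount", "Tobacco", "Amount"),
    ("Amount", "Alcohol", "Amount"),
    ("Amount", "Drug", "Amount"),
    ("Duration", "Tobacco", "Duration"),
    ("Duration", "Alcohol", "Duration"),
    ("Duration", "Drug", "Duration"),
    ("Frequency", "PhysicalActivity_Yes", "Frequency"),
    ("Frequency", "PhysicalActivity_No", "Frequency"),
    ("Frequency", "Tobacco", "Frequency"),
    ("Frequency", "Alcohol", "Frequency"),
    ("Frequency", "Drug", "Frequency"),
    ("Type", "Descendants_Yes", "Type"),
    ("Type", "Tobacco", "Type"),
    ("Type", "Alcohol", "Type"),
    ("Type", "Drug", "Type"),
)

RELATION_TRIPLES: frozenset[tuple[str, str, str]] = frozenset(
    _EXPLICIT_TRIPLES + tuple(("History", lab, "History") for lab in SDOH_LABELS)
)

#: (head label, relation type) pairs that must be present whenever the head is
#: annotated: substance triggers always carry their Status.
REQUIRED_RELATIONS: frozenset[tuple[str, str]] = frozenset(
    (lab, "Status") for lab in SUBSTANCE_LABELS
)

#: Name under which the StatusTime attribute is serialized in standoff files.
STATUS_ATTRIBUTE_NAME = "StatusTimeVal"


def legal_relation_types(head_label: str) -> tuple[str, ...]:
    """Relation types that may attach to a given SDoH head label."""
    if head_label not in SDOH_LABELS:
        raise SchemaError(f"not an SDoH label: {head_label!r}")
    return tuple(
        r for r in RELATION_TYPES
        if any(t[0] == r and t[1] == head_label for t in RELATION_TRIPLES)
    )


def entity_category(label: str) -> str:
    """Map one of the 25 SDoH labels to its SDoH category.

    Argument labels (StatusTime, History, ...) have no category and raise
    :class:`SchemaError`, as do unknown labels.
    """
    if label in ARGUMENT_LABELS:
        raise SchemaError(f"argument label has no SDoH category: {label!r}")
    try:
        return CATEGORY_MAP[label]
    except KeyError:
        raise SchemaError(f"unknown entity label: {label!r}") from None


def allowed_relation(rel_type: str, head_label: str, arg_label: str) -> bool:
    """True iff (rel_type, head_label, arg_label) is a legal triple."""
    if rel_type not in RELATION_TYPES:
        raise SchemaError(f"unknown relation type: {rel_type!r}")
    if head_label not in ALL_LABELS:
        raise SchemaError(f"unknown entity label: {head_label!r}")
    if arg_label not in ALL_LABELS:
        raise SchemaError(f"unknown entity label: {arg_label!r}")
    return (rel_type, head_label, arg_label) in RELATION_TRIPLES


# --------------------------------------------------------------------------- #
# Domain types


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [start, end) in code points over NFC text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SchemaError(f"invalid span: ({self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class EntityMention:
    id: str
    label: str
    span: Span
    surface: str

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise SchemaError(f"unknown entity label: {self.label!r}")


@dataclass(frozen=True)
class AttributeAssignment:
    """Consumption-status value attached to a StatusTime mention."""

    entity_id: str
    value: str

    def __post_init__(self) -> None:
        if self.value not in STATUS_VALUES:
            raise SchemaError(f"unknown status value: {self.value!r}")


@dataclass(frozen=True)
class RelationMention:
    type: str
    head_id: str
    arg_id: str

    def __post_init__(self) -> None:
        if self.type not in RELATION_TYPES:
            raise SchemaError(f"unknown relation type: {self.type!r}")


@dataclass
class AnnotatedDocument:
    """A clinical-note excerpt with its entity, attribute and relation annotations."""

    doc_id: str
    text: str
    entities: tuple[EntityMention, ...] = ()
    attributes: tuple[AttributeAssignment, ...] = ()
    relations: tuple[RelationMention, ...] = ()

    def __post_init__(self) -> None:
        self.entities = tuple(self.entities)
        self.attributes = tuple(self.attributes)
        self.relations = tuple(self.relations)

    # -- lookups ----------------------------------------------------------- #
    def entity_map(self) -> dict[str, EntityMention]:
        return {e.id: e for e in self.entities}

    def status_value(self, entity_id: str) -> str | None:
        """Attribute value of a StatusTime mention, or None."""
        for a in self.attributes:
            if a.entity_id == entity_id:
                return a.value
        return None

    def relations_from(self, head_id: str) -> tuple[RelationMention, ...]:
        return tuple(r for r in self.relations if r.head_id == head_id)

    def sdoh_entities(self) -> tuple[EntityMention, ...]:
        return tuple(e for e in self.entities if e.label in SDOH_LABELS)


@dataclass(frozen=True)
class Violation:
    """One broken invariant, as data: validation never raises."""

    rule: str
    subject: str
    message: str


def validate_document(doc: AnnotatedDocument) -> list[Violation]:
    """Check a document against the scheme; empty list means fully legal.

    Rules checked: unique ids; surfaces equal to the text at their spans;
    relation endpoints resolve and form legal triples; attributes target
    StatusTime mentions; every Status-linked StatusTime has exactly one
    value; substance triggers carry the required Status relation.
    Idempotent and insensitive to listing order (output is sorted).
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for e in doc.entities:
        if e.id in seen:
            out.append(Violation("duplicate-id", e.id, "entity id used more than once"))
        seen.add(e.id)
    emap = doc.entity_map()
    n = len(doc.text)
    for e in doc.entities:
        if e.span.end > n:
            out.append(Violation("span-out-of-range", e.id,
                                 f"span ({e.span.start}, {e.span.end}) exceeds text length {n}"))
        elif doc.text[e.span.start:e.span.end] != e.surface:
            out.append(Violation("surface-mismatch", e.id,
                                 f"surface {e.surface!r} != text at ({e.span.start}, {e.span.end})"))
    attr_counts: dict[str, int] = {}
    for a in doc.attributes:
        attr_counts[a.entity_id] = attr_counts.get(a.entity_id, 0) + 1
        target = emap.get(a.entity_id)
        if target is None:
            out.append(Violation("dangling-attribute", a.entity_id,
                                 "attribute targets a missing entity"))
        elif target.label != "StatusTime":
            out.append(Violation("attribute-target", a.entity_id,
                                 f"status attribute on {target.label}, expected StatusTime"))
    for eid, cnt in sorted(attr_counts.items()):
        if cnt > 1:
            out.append(Violation("duplicate-attribute", eid,
                                 f"{cnt} status values on one StatusTime mention"))
    heads_with: dict[str, set[str]] = {}
    for i, r in enumerate(doc.relations):
        subject = f"{r.type}({r.head_id},{r.arg_id})"
        head = emap.get(r.head_id)
        arg = emap.get(r.arg_id)
        if head is None or arg is None:
            out.append(Violation("dangling-relation", subject,
                                 "relation endpoint does not resolve"))
            continue
        if (r.type, head.label, arg.label) not in RELATION_TRIPLES:
            out.append(Violation("illegal-relation", subject,
                                 f"triple ({r.type}, {head.label}, {arg.label}) is not in the scheme"))
            continue
        heads_with.setdefault(r.head_id, set()).add(r.type)
        if r.type == "Status" and attr_counts.get(r.arg_id, 0) != 1:
            out.append(Violation("missing-status-value", r.arg_id,
                                 "Status-linked StatusTime must carry exactly one value"))
    for e in doc.entities:
        for head_label, rel in sorted(REQUIRED_RELATIONS):
            if e.label == head_label and rel not in heads_with.get(e.id, set()):
                out.append(Violation("missing-required-status", e.id,
                                     f"{e.label} trigger has no {rel} relation"))
    out.sort(key=lambda v: (v.rule, v.subject, v.message))
    return out


# --------------------------------------------------------------------------- #
# Machine-readable registry export


def registry() -> dict:
    """The scheme as plain data (labels, categories, triples, attribute values)."""
    return {
        "sdoh_labels": list(SDOH_LABELS),
        "argument_labels": list(ARGUMENT_LABELS),
        "categories": list(CATEGORIES),
        "category_map": dict(CATEGORY_MAP),
        "span_only_labels": list(SPAN_ONLY_LABELS),
        "status_values": list(STATUS_VALUES),
        "status_attribute": STATUS_ATTRIBUTE_NAME,
        "relation_triples": sorted(list(t) for t in RELATION_TRIPLES),
        "required_relations": sorted(list(p) for p in REQUIRED_RELATIONS),
    }


def to_annotation_conf() -> str:
    """Render the scheme as a BRAT ``annotation.conf`` file."""
    lines = ["[entities]"]
    lines += list(SDOH_LABELS) + list(ARGUMENT_LABELS)
    lines.append("")
    lines.append("[relations]")
    by_type: dict[str, list[tuple[str, str]]] = {}
    for rel, head, arg in sorted(RELATION_TRIPLES):
        by_type.setdefault(rel, []).append((head, arg))
    for rel in RELATION_TYPES:
        pairs = by_type.get(rel, [])
        heads = "|".join(sorted({h for h, _ in pairs}))
        args = "|".join(sorted({a for _, a in pairs}))
        lines.append(f"{rel}\tArg1:{heads}, Arg2:{args}")
    lines.append("")
    lines.append("[attributes]")
    lines.append(f"{STATUS_ATTRIBUTE_NAME}\tArg:StatusTime, Value:" + "|".join(STATUS_VALUES))
    lines.append("")
    lines.append("[events]")
    return "\n".join(lines) + "\n"
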