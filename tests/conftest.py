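"""Shared fixtures and oracle helpers for the test suite.

All corpora are generated programmatically by the synthetic module; no
fixture data is stored on disk.
"""
from __future__ import annotations

import random

import pytest

from sdohfr.schema import (
    AnnotatedDocument,
    AttributeAssignment,
    EntityMention,
    RelationMention,
    Span,
)
from sdohfr.synthetic import SynthConfig, generate_corpus


def make_doc(
    doc_id: str,
    text: str,
    entities: list[tuple[str, str, int, int]],
    relations: list[tuple[str, str, str]] = (),
    attributes: list[tuple[str, str]] = (),
) -> AnnotatedDocument:
    """Concise document builder: entities as (id, label, start, end)."""
    ents = tuple(
        EntityMention(eid, label, Span(start, end), text[start:end])
        for eid, label, start, end in entities
    )
    rels = tuple(RelationMention(t, h, a) for t, h, a in relations)
    attrs = tuple(AttributeAssignment(eid, value) for eid, value in attributes)
    return AnnotatedDocument(doc_id, text, ents, attrs, rels)


def perturb_doc(doc: AnnotatedDocument, rng: random.Random, jitter: int = 2) -> AnnotatedDocument:
    """A 'prediction' of ``doc`` with span boundaries jittered by up to
    ``jitter`` characters while keeping every span overlapping its gold
    span; labels, relations and status values are preserved."""
    new_entities = []
    for e in doc.entities:
        start = e.span.start + rng.randint(-jitter, jitter)
        end = e.span.end + rng.randint(-jitter, jitter)
        start = max(0, min(start, e.span.end - 1))
        end = min(len(doc.text), max(end, e.span.start + 1))
        if start >= end:
            start, end = e.span.start, e.span.end
        span = Span(start, end)
        new_entities.append(EntityMention(e.id, e.label, span, doc.text[start:end]))
    return AnnotatedDocument(
        doc.doc_id, doc.text, tuple(new_entities), doc.attributes, doc.relations
    )


def brute_force_max_matching(gold, pred, compatible) -> int:
    """Maximum bipartite matching size by exhaustive recursion (oracle)."""

    def rec(pi: int, used: frozenset) -> int:
        if pi == len(pred):
            return 0
        best = rec(pi + 1, used)
        for gi in range(len(gold)):
            if gi not in used and compatible(gold[gi], pred[pi]):
                best = max(best, 1 + rec(pi + 1, used | {gi}))
        return best

    return rec(0, frozenset())


@pytest.fixture(scope="session")
def synth_corpus():
    """A modest deterministic corpus shared across tests."""
    return generate_corpus(SynthConfig(n_docs=40, seed=7))


@pytest.fixture(scope="session")
def synth_corpus_rich():
    """A corpus with all categories forced on, for coverage of rare labels."""
    probs = {cat: 1.0 for cat in SynthConfig().category_probs}
    return generate_corpus(SynthConfig(n_docs=25, seed=11, category_probs=probs))
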