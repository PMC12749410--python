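"""Predictor contract: anything that maps section text to an event sequence.

The extraction model proper is a fine-tuned seq2seq language model; this
toolkit treats it as a pluggable backend behind a minimal contract
(``name``, ``predict(text) -> str``, ``deterministic``) so that the whole
pipeline — linearization, grounding, evaluation — is testable without GPU
weights.  Two reference predictors ship with the package:

* :class:`OraclePredictor` replays the gold serialization of a reference
  corpus (keyed by section text) — the upper bound used by the end-to-end
  identity suites;
* :class:`LexiconPredictor` is a deterministic rule-based baseline built
  from the scheme's canonical trigger surfaces, with simple cue words for
  substance status.

``FinetuneConfig`` plus :func:`build_training_pairs` are the glue for
fine-tuning a real model elsewhere: they produce the (section text,
target sequence) pairs and record the training hyperparameters; no deep
learning framework is imported here.
"""
from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Protocol, Sequence, runtime_checkable

from ._text import nfc, occurrences
from .schema import SDOH_LABELS, SUBSTANCE_LABELS, AnnotatedDocument, validate_document
from .serializer import EventArg, SDoHEvent, serialize_document, serialize_events


@runtime_checkable
class Predictor(Protocol):
    """Anything producing a linearized event sequence from section text."""

    name: str
    deterministic: bool

    def predict(self, text: str) -> str:  # pragma: no cover - protocol
        ...


class OraclePredictor:
    """Replays gold serializations of a reference corpus, keyed by text.

    Text absent from the reference corpus predicts the empty sequence.
    """

    name = "oracle"
    deterministic = True

    def __init__(self, corpus: Sequence[AnnotatedDocument]):
        self._by_text = {nfc(doc.text): serialize_document(doc) for doc in corpus}

    def predict(self, text: str) -> str:
        return self._by_text.get(nfc(text), "")


# --------------------------------------------------------------------------- #
# Rule-based baseline

#: Canonical trigger surfaces per SDoH label (a small, deterministic
#: keyword baseline — high precision, low recall by design).
TRIGGER_LEXICON: dict[str, str] = {
    "Vit seul": "Living_Alone",
    "Vit avec sa soeur": "Living_WithOthers",
    "Vit avec ses parents": "Living_WithOthers",
    "Vit en EHPAD": "Living_WithOthers",
    "Célibataire": "MaritalStatus_Single",
    "Pas de conjoint": "MaritalStatus_Single",
    "Mariée": "MaritalStatus_InRelationship",
    "Marié": "MaritalStatus_InRelationship",
    "Vit en concubinage": "MaritalStatus_InRelationship",
    "Pacsé": "MaritalStatus_InRelationship",
    "Divorcé": "MaritalStatus_Divorced",
    "Veuf": "MaritalStatus_Widowed",
    "Veuve": "MaritalStatus_Widowed",
    "Deux filles": "Descendants_Yes",
    "Trois petits-enfants": "Descendants_Yes",
    "Pas d’enfant": "Descendants_No",
    "Sans enfant": "Descendants_No",
    "Soudeur": "Job",
    "Travaille toujours": "Employment_Working",
    "Il est au chômage": "Employment_Unemployed",
    "Patient étudiant": "Employment_Student",
    "Retraité": "Employment_Pensioner",
    "A la retraite": "Employment_Pensioner",
    "Mère au foyer": "Employment_Other",
    "Alcool": "Alcohol",
    "Ethylisme": "Alcohol",
    "OH": "Alcohol",
    "Tabac": "Tobacco",
    "Tabagisme": "Tobacco",
    "Consommation tabagique": "Tobacco",
    "Cannabis": "Drug",
    "Héroïne": "Drug",
    "drogue": "Drug",
    "Sans domicile fixe": "Housing_No",
    "Sédentaire": "PhysicalActivity_No",
    "Pas d’activité sportive": "PhysicalActivity_No",
    "RSA": "Income",
    "AAH": "Income",
}

#: Substance-status cue phrases, most specific first.  Past cues win over
#: none cues; with no cue at all the status defaults to current.
PAST_CUES: tuple[str, ...] = ("sevré", "sevrée", "ancien", "ancienne", "arrêté", "stoppé")
NONE_CUES: tuple[str, ...] = ("ne consomme pas", "pas de", "pas d’", "non", "0")


def lexicon_extract(text: str) -> list[SDoHEvent]:
    """Deterministic longest-match trigger extraction with status cues.

    Matches lexicon surfaces case-insensitively, keeps the longest match
    at each position and discards overlaps; substance triggers receive a
    Status argument from the nearest cue phrase (past cues, then none
    cues, else current with the trigger surface standing in as the
    StatusTime span).
    """
    text = nfc(text)
    hits: list[tuple[int, int, str, str]] = []  # (start, -len, surface, label)
    for surface, label in TRIGGER_LEXICON.items():
        spans, _level = occurrences(surface, text)
        for s in spans:
            hits.append((s.start, -(s.end - s.start), text[s.start:s.end], label))
    hits.sort()
    events: list[SDoHEvent] = []
    last_end = -1
    for start, neg_len, surface, label in hits:
        end = start - neg_len
        if start < last_end:
            continue
        last_end = end
        args: tuple[EventArg, ...] = ()
        if label in SUBSTANCE_LABELS:
            args = (_status_arg(text, surface),)
        events.append(SDoHEvent(label, surface, None, args))
    return events


def _status_arg(text: str, trigger_surface: str) -> EventArg:
    for cues, value in ((PAST_CUES, "past"), (NONE_CUES, "none")):
        for cue in cues:
            spans, _ = occurrences(cue, text)
            if spans:
                s = spans[0]
                return EventArg("Status", value, text[s.start:s.end])
    return EventArg("Status", "current", trigger_surface)


class LexiconPredictor:
    """Rule-based baseline serializing :func:`lexicon_extract` output."""

    name = "lexicon"
    deterministic = True

    def predict(self, text: str) -> str:
        return serialize_events(lexicon_extract(text))


# --------------------------------------------------------------------------- #
# Fine-tuning glue (configuration only; no framework import)


@dataclass(frozen=True)
class FinetuneConfig:
    """Hyperparameters for fine-tuning a seq2seq backbone elsewhere."""

    model_name: str = "google/flan-t5-large"
    epochs: int = 10
    learning_rate: float = 5e-5
    batch_size: int = 8
    max_source_length: int = 512
    max_target_length: int = 512
    device: str = "cuda"

    def to_dict(self) -> dict:
        return asdict(self)


def build_training_pairs(
    corpus: Sequence[AnnotatedDocument],
) -> list[tuple[str, str]]:
    """(section text, target sequence) pairs in stable doc_id order.

    The input is the raw section text with no prompt prefix; the target is
    the document's linearized event sequence.  Documents violating the
    scheme are skipped with a warning.
    """
    pairs = []
    for doc in sorted(corpus, key=lambda d: d.doc_id):
        if validate_document(doc):
            warnings.warn(f"{doc.doc_id}: skipped invalid document", stacklevel=2)
            continue
        pairs.append((doc.text, serialize_document(doc)))
    return pairs
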