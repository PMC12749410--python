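"""Seeded generator of gold-annotated French social-history sections.

Documents emulate the shape of short social-history excerpts from French
hospital notes: a section header ("Mode de vie :") followed by 1–8
telegraphic sentences, each realizing one SDoH category.  The template
bank is seeded from the scheme's canonical example surfaces ("Vit seul",
"Tabac", "Ne consomme pas d'alcool", ...), and the default prevalence
profile skews toward the categories that dominate real corpora — living
condition, marital status, descendants, job, tobacco and alcohol are
frequent; income, education and housing instability are rare.

Every generated document passes schema validation, every substance trigger
carries a Status relation, and spans are exact by construction, so the
corpus drives the round-trip suites (standoff IO, serialization,
grounding) without any external data.  Repeated surfaces across sentences
("par jour", "non", "0", "il y a 8 ans") are generated on purpose to
exercise the grounding disambiguation rules.  Generation is fully
deterministic for a fixed seed; no language model is involved.
"""
from __future__ import annotations

import random
import unicodedata
from dataclasses import dataclass, field, replace

from .errors import ConfigError
from .schema import (
    CATEGORIES,
    CATEGORY_MAP,
    STATUS_VALUES,
    SUBSTANCE_LABELS,
    AnnotatedDocument,
    AttributeAssignment,
    EntityMention,
    RelationMention,
    Span,
    validate_document,
)

# --------------------------------------------------------------------------- #
# Template mini-language


@dataclass(frozen=True)
class Chunk:
    """A literal piece of sentence text, optionally annotated.

    ``role`` is ``"trigger"`` or a relation type; ``value`` carries the
    status for Status chunks (the realized mention is a StatusTime entity).
    """

    text: str
    role: str | None = None
    value: str | None = None


@dataclass(frozen=True)
class OptGroup:
    """Chunks included together with the argument probability named by ``key``."""

    key: str  # "amount" | "duration" | "frequency" | "type" | "history"
    chunks: tuple[Chunk, ...]


@dataclass(frozen=True)
class Template:
    label: str
    items: tuple[Chunk | OptGroup, ...]
    status: str | None = None  # substances: which status this template realizes


def _t(label: str, *items: Chunk | OptGroup, status: str | None = None) -> Template:
    return Template(label, tuple(items), status)


def _c(text: str, role: str | None = None, value: str | None = None) -> Chunk:
    return Chunk(text, role, value)


def _g(key: str, *chunks: Chunk) -> OptGroup:
    return OptGroup(key, tuple(chunks))


# Sentences are composed so that, within any document the generator can
# produce, every trigger surface has its gold occurrence as the leftmost
# unconsumed exact match and every argument's gold occurrence is the one
# nearest its trigger — the greedy grounding rules then recover all spans.
TEMPLATE_BANK: tuple[Template, ...] = (
    # living condition ----------------------------------------------------- #
    _t("Living_Alone", _c("Vit seul", "trigger"), _c(".")),
    _t("Living_Alone", _c("Vit seule", "trigger"), _c(".")),
    _t("Living_WithOthers", _c("Vit avec sa soeur", "trigger"), _c(".")),
    _t("Living_WithOthers", _c("Vit avec ses parents", "trigger"), _c(".")),
    _t("Living_WithOthers", _c("Vit avec son épouse et ses enfants", "trigger"), _c(".")),
    _t("Living_WithOthers", _c("Vit en EHPAD", "trigger"), _c(".")),
    # marital status ------------------------------------------------------- #
    _t("MaritalStatus_Single", _c("Célibataire sans enfant", "trigger"), _c(".")),
    _t("MaritalStatus_Single", _c("Pas de conjoint", "trigger"), _c(".")),
    _t("MaritalStatus_InRelationship", _c("Mariée", "trigger"), _c(".")),
    _t("MaritalStatus_InRelationship", _c("Vit en concubinage", "trigger"), _c(".")),
    _t("MaritalStatus_InRelationship", _c("Vit avec sa compagne", "trigger"), _c(".")),
    _t("MaritalStatus_InRelationship", _c("Pacsé", "trigger"), _c(".")),
    _t("MaritalStatus_Divorced", _c("Divorcé", "trigger"), _c(".")),
    _t("MaritalStatus_Divorced",
       _c("Plus de contact avec le père de ses enfants", "trigger"), _c(".")),
    _t("MaritalStatus_Widowed", _c("Veuf", "trigger"), _c(".")),
    _t("MaritalStatus_Widowed", _c("Veuve", "trigger"), _c(".")),
    # descendants ---------------------------------------------------------- #
    _t("Descendants_Yes", _c("Deux filles", "trigger"), _c(".")),
    _t("Descendants_Yes", _c("1 fils adopté", "trigger"), _c(".")),
    _t("Descendants_Yes", _c("Trois petits-enfants", "trigger"), _c(".")),
    _t("Descendants_Yes", _c("Courses faites par sa fille", "trigger"), _c(".")),
    _t("Descendants_Yes",
       _c("A des descendants", "trigger"),
       _g("amount", _c(" : "), _c("2 enfants", "Amount")),
       _g("type", _c(", type "), _c("Enfants", "Type")),
       _c(".")),
    _t("Descendants_Yes",
       _c("Trois enfants", "trigger"),
       _g("type", _c(", surtout des "), _c("petits-enfants", "Type")),
       _c(".")),
    _t("Descendants_No", _c("Pas d’enfant", "trigger"), _c(".")),
    _t("Descendants_No", _c("Sans enfant", "trigger"), _c(".")),
    _t("Descendants_No", _c("Enceinte de son premier enfant", "trigger"), _c(".")),
    # job / last job ------------------------------------------------------- #
    _t("Job", _c("Courtier dans le textile", "trigger"), _c(".")),
    _t("Job", _c("Travaille dans le batiment", "trigger"), _c(".")),
    _t("Job", _c("Soudeur", "trigger"), _c(".")),
    _t("Last_job", _c("Dernier emploi : "), _c("couvreur", "trigger"), _c(".")),
    _t("Last_job", _c("Dernier métier exercé : "), _c("boulangère", "trigger"), _c(".")),
    # employment status ---------------------------------------------------- #
    _t("Employment_Working", _c("Travaille toujours", "trigger"), _c(".")),
    _t("Employment_Working", _c("En reconversion professionnelle", "trigger"), _c(".")),
    _t("Employment_Working", _c("Agent de ménage", "trigger"), _c(".")),
    _t("Employment_Working", _c("Maître d’œuvre", "trigger"), _c(".")),
    _t("Employment_Unemployed", _c("Vient de terminer son CDD", "trigger"), _c(".")),
    _t("Employment_Unemployed", _c("Il est au chômage", "trigger"), _c(".")),
    _t("Employment_Student", _c("Actuellement lycéen", "trigger"), _c(".")),
    _t("Employment_Student", _c("Est "), _c("en première année de BTS", "trigger"), _c(".")),
    _t("Employment_Student", _c("Patient étudiant", "trigger"), _c(".")),
    _t("Employment_Pensioner", _c("Retraité", "trigger"), _c(".")),
    _t("Employment_Pensioner", _c("A la retraite", "trigger"), _c(".")),
    _t("Employment_Pensioner", _c("Ancien magasinier", "trigger"), _c(".")),
    _t("Employment_Other", _c("Il a été courtier dans le textile", "trigger"), _c(".")),
    _t("Employment_Other", _c("Elle a travaillé comme dentiste", "trigger"), _c(".")),
    _t("Employment_Other",
       _c("Travailleur handicapé et ne travaille plus depuis 2011", "trigger"), _c(".")),
    _t("Employment_Other", _c("En invalidité", "trigger"), _c(".")),
    _t("Employment_Other", _c("Mère au foyer", "trigger"), _c(".")),
    # alcohol -------------------------------------------------------------- #
    _t("Alcohol",
       _c("Alcool", "trigger"), _c(" : consommation "),
       _c("actuelle", "Status", "current"),
       _g("amount", _c(", "), _c("3 verres de vin", "Amount")),
       _g("frequency", _c(", "), _c("chaque soir", "Frequency")),
       _c("."), status="current"),
    _t("Alcohol",
       _c("OH", "trigger"), _c(" "),
       _c("chronique", "Status", "current"),
       _g("type", _c(", plutôt de la "), _c("bière", "Type")),
       _g("frequency", _c(", "), _c("par mois", "Frequency")),
       _c("."), status="current"),
    _t("Alcohol",
       _c("Intoxication ethylique", "trigger"), _c(" "),
       _c("active", "Status", "current"),
       _c("."), status="current"),
    _t("Alcohol",
       _c("Ethylisme", "trigger"), _c(" "),
       _c("arrêté", "Status", "past"),
       _g("history", _c(" "), _c("il y a 15 ans", "History")),
       _g("duration", _c(", après une consommation "), _c("pendant 30 ans", "Duration")),
       _c("."), status="past"),
    _t("Alcohol",
       _c("CAD", "trigger"), _c(" "),
       _c("sevrée", "Status", "past"),
       _g("duration", _c(", exposition "), _c("pendant 15 ans", "Duration")),
       _c("."), status="past"),
    _t("Alcohol",
       _c("Ne consomme pas", "Status", "none"), _c(" d’"),
       _c("alcool", "trigger"),
       _c("."), status="none"),
    # tobacco -------------------------------------------------------------- #
    _t("Tobacco",
       _c("Tabagisme", "trigger"), _c(" "),
       _c("actif", "Status", "current"),
       _g("amount", _c(" à "), _c("17 cigarettes", "Amount")),
       _g("frequency", _c(", "), _c("quotidiennement", "Frequency")),
       _c("."), status="current"),
    _t("Tobacco",
       _c("Consommation tabagique", "trigger"), _c(" "),
       _c("en cours", "Status", "current"),
       _c("."), status="current"),
    _t("Tobacco",
       _c("Tabac", "trigger"), _c(" "),
       _c("sevré", "Status", "past"),
       _g("history", _c(" "), _c("il y a 8 ans", "History")),
       _g("duration", _c(", fumait "), _c("pendant 20 ans", "Duration")),
       _g("amount", _c(", "), _c("20 paquets de cigarettes", "Amount")),
       _c("."), status="past"),
    _t("Tobacco",
       _c("Tabagisme", "trigger"), _c(" "),
       _c("ancien", "Status", "past"),
       _g("type", _c(", "), _c("cigarette", "Type")),
       _c("."), status="past"),
    _t("Tobacco",
       _c("Tabac", "trigger"), _c(" : "),
       _c("non", "Status", "none"),
       _c("."), status="none"),
    # drug ----------------------------------------------------------------- #
    _t("Drug",
       _c("Cannabis", "trigger"), _c(" "),
       _c("fumé", "Status", "current"),
       _g("frequency", _c(", "), _c("occasionnellement", "Frequency")),
       _c("."), status="current"),
    _t("Drug",
       _c("Héroïne en fumette", "trigger"), _c(", usage "),
       _c("régulier", "Status", "current"),
       _c("."), status="current"),
    _t("Drug",
       _c("drogue", "trigger"), _c(" "),
       _c("stoppée", "Status", "past"),
       _g("type", _c(", type "), _c("cocaïne", "Type")),
       _g("history", _c(", arrêt "), _c("il y a 3 ans", "History")),
       _c("."), status="past"),
    _t("Drug",
       _c("Drogue", "trigger"), _c(" : "),
       _c("0", "Status", "none"),
       _c("."), status="none"),
    # housing -------------------------------------------------------------- #
    _t("Housing_Yes", _c("Habite à Nantes", "trigger"), _c(".")),
    _t("Housing_Yes", _c("Pas d’aides à domicile", "trigger"), _c(".")),
    _t("Housing_Yes", _c("Vit dans une maison", "trigger"), _c(".")),
    _t("Housing_No", _c("Sans domicile fixe", "trigger"), _c(".")),
    _t("Housing_No", _c("Hébergé chez des tiers", "trigger"), _c(".")),
    # physical activity ---------------------------------------------------- #
    _t("PhysicalActivity_Yes",
       _c("Fait du vélo", "trigger"),
       _g("frequency", _c(", "), _c("3 fois par semaine", "Frequency")),
       _c(".")),
    _t("PhysicalActivity_Yes", _c("Marche 30 min par jour", "trigger"), _c(".")),
    _t("PhysicalActivity_No", _c("Pas d’activité sportive", "trigger"), _c(".")),
    _t("PhysicalActivity_No", _c("Sédentaire", "trigger"), _c(".")),
    _t("PhysicalActivity_No", _c("Performance status 3", "trigger"), _c(".")),
    _t("PhysicalActivity_No", _c("Marche avec une canne", "trigger"), _c(", sort peu.")),
    # income / education / ethnicity --------------------------------------- #
    _t("Income", _c("Perçoit le "), _c("RSA", "trigger"), _c(".")),
    _t("Income", _c("Bénéficie de l’"), _c("AAH", "trigger"), _c(".")),
    _t("Education", _c("Niveau d’études : "), _c("Certificat d’étude", "trigger"), _c(".")),
    _t("Education", _c("A un "), _c("BTS Informatique", "trigger"), _c(".")),
    _t("Education", _c("A une "), _c("Licence en droit", "trigger"), _c(".")),
    _t("Ethnicity", _c("Originaire du Maroc", "trigger"), _c(".")),
    _t("Ethnicity", _c("Originaire d’Érythrée", "trigger"), _c(".")),
)

#: Relative weights for picking a label within an included category,
#: approximating the skew of real corpora (e.g. Living_WithOthers and
#: MaritalStatus_InRelationship dominate their categories).
DEFAULT_LABEL_WEIGHTS: dict[str, float] = {
    "Living_Alone": 1.0, "Living_WithOthers": 2.0,
    "MaritalStatus_Single": 0.6, "MaritalStatus_InRelationship": 4.0,
    "MaritalStatus_Divorced": 0.8, "MaritalStatus_Widowed": 0.8,
    "Descendants_Yes": 6.0, "Descendants_No": 1.0,
    "Job": 2.0, "Last_job": 1.8,
    "Employment_Working": 1.5, "Employment_Unemployed": 0.5,
    "Employment_Student": 0.2, "Employment_Pensioner": 1.5, "Employment_Other": 0.5,
    "Alcohol": 1.0, "Tobacco": 1.0, "Drug": 1.0,
    "Housing_Yes": 6.0, "Housing_No": 0.5,
    "PhysicalActivity_Yes": 3.0, "PhysicalActivity_No": 1.0,
    "Income": 1.0, "Education": 1.0, "Ethnicity": 1.0,
}

#: Default per-category inclusion probabilities, skewed toward the
#: categories that dominate real social-history sections.
DEFAULT_CATEGORY_PROBS: dict[str, float] = {
    "living condition": 0.75,
    "marital status": 0.70,
    "descendants": 0.65,
    "employment status": 0.45,
    "job": 0.55,
    "tobacco": 0.60,
    "alcohol": 0.55,
    "drug": 0.15,
    "housing": 0.35,
    "education": 0.07,
    "physical activity": 0.12,
    "income": 0.06,
    "ethnicity/country of birth": 0.08,
}

DEFAULT_STATUS_DIST: dict[str, float] = {"current": 0.45, "past": 0.35, "none": 0.20}

DEFAULT_ARG_PROBS: dict[str, float] = {
    "amount": 0.55, "duration": 0.30, "frequency": 0.40, "type": 0.35, "history": 0.35,
}

HEADERS: tuple[str, ...] = ("Mode de vie :", "Contexte social :", "Habitus :")


@dataclass
class SynthConfig:
    """Study conditions for corpus generation (deterministic given ``seed``)."""

    n_docs: int = 340
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS))
    status_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATUS_DIST))
    arg_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ARG_PROBS))
    label_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_WEIGHTS))
    templates: tuple[Template, ...] = TEMPLATE_BANK
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ConfigError("n_docs must be non-negative")
        if set(self.category_probs) != set(CATEGORIES):
            raise ConfigError("category_probs must cover exactly the 13 categories")
        for name, p in {**self.category_probs, **self.arg_probs}.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability out of range for {name!r}: {p}")
        if set(self.status_dist) != set(STATUS_VALUES):
            raise ConfigError("status_dist must cover current/past/none")
        total = sum(self.status_dist.values())
        if any(p < 0 for p in self.status_dist.values()) or abs(total - 1.0) > 1e-9:
            raise ConfigError("status_dist must be a probability distribution")
        for tpl in self.templates:
            _check_template(tpl)


def _check_template(tpl: Template) -> None:
    from .schema import RELATION_TRIPLES, SDOH_LABELS

    if tpl.label not in SDOH_LABELS:
        raise ConfigError(f"template label {tpl.label!r} is not an SDoH label")
    roles = [c.role for item in tpl.items
             for c in (item.chunks if isinstance(item, OptGroup) else (item,))
             if c.role is not None]
    if roles.count("trigger") != 1:
        raise ConfigError(f"template for {tpl.label} must have exactly one trigger")
    for item in tpl.items:
        chunks = item.chunks if isinstance(item, OptGroup) else (item,)
        for c in chunks:
            if c.role in (None, "trigger"):
                continue
            arg_label = "StatusTime" if c.role == "Status" else c.role
            if (c.role, tpl.label, arg_label) not in RELATION_TRIPLES:
                raise ConfigError(
                    f"template for {tpl.label} uses illegal relation {c.role}")
            if c.role == "Status" and c.value not in STATUS_VALUES:
                raise ConfigError(f"Status chunk needs a status value in {tpl.label}")
    if tpl.label in SUBSTANCE_LABELS and not any(r == "Status" for r in roles):
        raise ConfigError(f"substance template {tpl.label} lacks a Status chunk")


# --------------------------------------------------------------------------- #
# Generation

_CATEGORY_LABELS: dict[str, list[str]] = {}
for _lab, _cat in CATEGORY_MAP.items():
    _CATEGORY_LABELS.setdefault(_cat, []).append(_lab)

_ARG_PROB_KEY = {"Amount": "amount", "Duration": "duration", "Frequency": "frequency",
                 "Type": "type", "History": "history"}


def _realize(tpl: Template, rng: random.Random, arg_probs: dict[str, float]):
    """Instantiate one template: (sentence_text, [(local_span, role, value)])."""
    parts: list[str] = []
    marks: list[tuple[int, int, str, str | None]] = []
    pos = 0

    def emit(chunk: Chunk) -> None:
        nonlocal pos
        if chunk.role is not None:
            marks.append((pos, pos + len(chunk.text), chunk.role, chunk.value))
        parts.append(chunk.text)
        pos += len(chunk.text)

    for item in tpl.items:
        if isinstance(item, OptGroup):
            if rng.random() < arg_probs.get(item.key, 0.0):
                for c in item.chunks:
                    emit(c)
        else:
            emit(item)
    return "".join(parts), marks


def generate_document(config: SynthConfig, rng: random.Random,
                      doc_id: str = "synth-0000") -> AnnotatedDocument:
    """Generate one gold-annotated social-history section."""
    by_label: dict[str, list[Template]] = {}
    for tpl in config.templates:
        by_label.setdefault(tpl.label, []).append(tpl)

    sentences: list[tuple[str, list[tuple[int, int, str, str | None]], str]] = []
    for cat in CATEGORIES:
        if rng.random() >= config.category_probs[cat]:
            continue
        labels = [lab for lab in _CATEGORY_LABELS[cat] if lab in by_label]
        if not labels:
            continue
        weights = [config.label_weights.get(lab, 1.0) for lab in labels]
        label = rng.choices(labels, weights=weights, k=1)[0]
        pool = by_label[label]
        if label in SUBSTANCE_LABELS:
            status = rng.choices(list(config.status_dist), weights=list(
                config.status_dist.values()), k=1)[0]
            pool = [t for t in pool if t.status == status] or pool
        tpl = rng.choice(pool)
        text, marks = _realize(tpl, rng, config.arg_probs)
        sentences.append((text, marks, tpl.label))

    rng.shuffle(sentences)
    header = rng.choice(HEADERS)
    pieces = [header, "\n"]
    offset = len(header) + 1
    entities: list[EntityMention] = []
    attributes: list[AttributeAssignment] = []
    relations: list[RelationMention] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter}"

    for si, (stext, marks, label) in enumerate(sentences):
        if si:
            pieces.append(" ")
            offset += 1
        trig_id = None
        pending: list[tuple[str, str, str | None]] = []  # (entity_id, role, value)
        for start, end, role, value in marks:
            span = Span(offset + start, offset + end)
            eid = new_id()
            if role == "trigger":
                entities.append(EntityMention(eid, label, span, stext[start:end]))
                trig_id = eid
            else:
                arg_label = "StatusTime" if role == "Status" else role
                entities.append(EntityMention(eid, arg_label, span, stext[start:end]))
                if role == "Status":
                    attributes.append(AttributeAssignment(eid, value))
                pending.append((eid, role, value))
        assert trig_id is not None
        for eid, role, _value in pending:
            relations.append(RelationMention(role, trig_id, eid))
        pieces.append(stext)
        offset += len(stext)

    text = "".join(pieces)
    assert unicodedata.normalize("NFC", text) == text
    doc = AnnotatedDocument(doc_id, text, tuple(entities), tuple(attributes), tuple(relations))
    violations = validate_document(doc)
    if violations:  # a template bank bug, not a data condition
        raise AssertionError(f"generator produced invalid document: {violations}")
    return doc


def generate_corpus(config: SynthConfig | None = None) -> list[AnnotatedDocument]:
    """Generate ``config.n_docs`` documents, deterministic for a fixed seed."""
    config = config or SynthConfig()
    config.validate()
    rng = random.Random(config.seed)
    return [
        generate_document(config, rng, doc_id=f"synth-{i:04d}")
        for i in range(config.n_docs)
    ]
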