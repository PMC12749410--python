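"""Synthetic gold-corpus generator: determinism, validity, distributions."""
from __future__ import annotations

import math
import random

import pytest

from sdohfr.errors import ConfigError
from sdohfr.schema import CATEGORY_MAP, SUBSTANCE_LABELS, entity_category, validate_document
from sdohfr.synthetic import (
    DEFAULT_CATEGORY_PROBS,
    TEMPLATE_BANK,
    Chunk,
    OptGroup,
    SynthConfig,
    generate_corpus,
)

# Canonical example surfaces of the scheme that the bank must realize.
CANONICAL_SURFACES = [
    "Vit seul", "Vit avec sa soeur", "Vit avec ses parents",
    "Vit avec son épouse et ses enfants", "Vit en EHPAD",
    "Célibataire sans enfant", "Pas de conjoint", "Mariée", "Vit en concubinage",
    "Vit avec sa compagne", "Pacsé", "Divorcé",
    "Plus de contact avec le père de ses enfants", "Veuf", "Veuve",
    "Deux filles", "1 fils adopté", "Trois petits-enfants",
    "Courses faites par sa fille", "Pas d’enfant", "Sans enfant",
    "Enceinte de son premier enfant",
    "Courtier dans le textile", "Travaille dans le batiment", "Soudeur",
    "Travaille toujours", "En reconversion professionnelle", "Agent de ménage",
    "Maître d’œuvre", "Vient de terminer son CDD", "Il est au chômage",
    "Actuellement lycéen", "en première année de BTS", "Patient étudiant",
    "Retraité", "A la retraite", "Ancien magasinier",
    "Il a été courtier dans le textile", "Elle a travaillé comme dentiste",
    "Travailleur handicapé et ne travaille plus depuis 2011",
    "En invalidité", "Mère au foyer",
    "Alcool", "Ethylisme", "CAD", "OH", "Intoxication ethylique",
    "Tabac", "Tabagisme", "Consommation tabagique",
    "Héroïne en fumette", "Cannabis", "drogue",
    "Habite à Nantes", "Pas d’aides à domicile", "Vit dans une maison",
    "Sans domicile fixe", "Hébergé chez des tiers",
    "Fait du vélo", "Marche 30 min par jour", "Pas d’activité sportive",
    "Sédentaire", "Performance status 3", "Marche avec une canne",
    "RSA", "AAH", "Certificat d’étude", "BTS Informatique", "Licence en droit",
    "Originaire du Maroc", "Originaire d’Érythrée",
    "Ne consomme pas d’alcool", "il y a 8 ans", "pendant 20 ans",
    "20 paquets de cigarettes", "3 verres de vin", "2 enfants",
    "par jour", "par mois", "occasionnellement",
    "Enfants", "petits-enfants", "vin", "bière", "cigarette", "cocaïne", "cannabis",
]


def bank_text() -> str:
    parts = []
    for tpl in TEMPLATE_BANK:
        for item in tpl.items:
            chunks = item.chunks if isinstance(item, OptGroup) else (item,)
            parts.extend(c.text for c in chunks)
        parts.append("\n")
    return "".join(parts)


class TestDeterminism:
    def test_same_seed_gives_identical_corpora(self):
        cfg = SynthConfig(n_docs=15, seed=5)
        a = generate_corpus(cfg)
        b = generate_corpus(SynthConfig(n_docs=15, seed=5))
        assert [(d.doc_id, d.text, d.entities, d.attributes, d.relations) for d in a] == [
            (d.doc_id, d.text, d.entities, d.attributes, d.relations) for d in b]

    def test_different_seeds_differ(self):
        a = generate_corpus(SynthConfig(n_docs=15, seed=5))
        b = generate_corpus(SynthConfig(n_docs=15, seed=6))
        assert [d.text for d in a] != [d.text for d in b]

    def test_default_size_matches_reference_corpus(self):
        assert SynthConfig().n_docs == 340


class TestValidity:
    def test_all_documents_pass_schema_validation(self):
        # many documents across several seeds
        for seed in range(5):
            for doc in generate_corpus(SynthConfig(n_docs=80, seed=seed)):
                assert validate_document(doc) == []

    def test_every_substance_trigger_has_status(self, synth_corpus_rich):
        for doc in synth_corpus_rich:
            for e in doc.entities:
                if e.label in SUBSTANCE_LABELS:
                    rels = [r for r in doc.relations_from(e.id) if r.type == "Status"]
                    assert len(rels) == 1

    def test_spans_are_exact(self, synth_corpus):
        for doc in synth_corpus:
            for e in doc.entities:
                assert doc.text[e.span.start:e.span.end] == e.surface


class TestConfig:
    def test_forced_category_always_appears(self):
        probs = dict(DEFAULT_CATEGORY_PROBS)
        probs["tobacco"] = 1.0
        for doc in generate_corpus(SynthConfig(n_docs=30, seed=1, category_probs=probs)):
            assert any(e.label == "Tobacco" for e in doc.entities)

    def test_all_zero_probabilities_give_header_only_documents(self):
        probs = {cat: 0.0 for cat in DEFAULT_CATEGORY_PROBS}
        docs = generate_corpus(SynthConfig(n_docs=5, seed=1, category_probs=probs))
        for doc in docs:
            assert doc.entities == ()
            assert doc.text.endswith(":\n") or doc.text.rstrip().endswith(":")

    def test_invalid_probability_is_config_error(self):
        probs = dict(DEFAULT_CATEGORY_PROBS)
        probs["tobacco"] = 1.5
        with pytest.raises(ConfigError):
            generate_corpus(SynthConfig(n_docs=1, category_probs=probs))

    def test_bad_status_distribution_is_config_error(self):
        with pytest.raises(ConfigError):
            generate_corpus(SynthConfig(
                n_docs=1, status_dist={"current": 0.9, "past": 0.9, "none": 0.2}))


class TestDistribution:
    def test_category_frequencies_within_three_sigma(self):
        n = 2000
        docs = generate_corpus(SynthConfig(n_docs=n, seed=123))
        counts = {cat: 0 for cat in DEFAULT_CATEGORY_PROBS}
        for doc in docs:
            cats = {entity_category(e.label) for e in doc.entities
                    if e.label in CATEGORY_MAP}
            for cat in cats:
                counts[cat] += 1
        for cat, p in DEFAULT_CATEGORY_PROBS.items():
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(counts[cat] - n * p) <= 3 * sigma, (cat, counts[cat], n * p)

    def test_canonical_surfaces_all_in_bank(self):
        text = bank_text().lower()
        for surface in CANONICAL_SURFACES:
            assert surface.lower() in text, surface

    def test_canonical_surfaces_generated_with_positive_probability(self):
        # with all categories forced and args likely, a few hundred docs
        # exercise every template
        probs = {cat: 1.0 for cat in DEFAULT_CATEGORY_PROBS}
        args = {k: 0.9 for k in ("amount", "duration", "frequency", "type", "history")}
        corpus = generate_corpus(SynthConfig(
            n_docs=400, seed=17, category_probs=probs, arg_probs=args))
        blob = "\n".join(d.text for d in corpus).lower()
        for surface in CANONICAL_SURFACES:
            assert surface.lower() in blob, surface
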