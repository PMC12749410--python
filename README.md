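# sdohfr — social determinants of health extraction for French clinical notes

Social determinants of health (SDoH) — living situation, marital status,
descendants, employment, substance use, housing, education, physical
activity, income, country of birth — strongly shape health outcomes, yet
structured EHR fields (ICD-10 Z-codes) capture only a few percent of what
clinicians actually write in free text. `sdohfr` is a toolkit for the
clinical-NLP researcher or data-warehouse engineer who wants to extract
and evaluate SDoH from the *social-history sections* of French clinical
notes, end to end:

* **Annotation scheme** — 25 SDoH entity labels covering 13 categories,
  6 argument labels (StatusTime, History, Duration, Amount, Frequency,
  Type) and a typed relation table; substance use (tobacco, alcohol,
  drug) is an *event*: a trigger span plus a required `Status` relation
  to a StatusTime mention valued `current | past | none`.
* **BRAT standoff IO** — lossless `.txt`/`.ann` reading and writing with
  schema validation.
* **Section extraction** — rule-based, header-lexicon detection of the
  social-history section in a full note.
* **Seq2seq linearization and grounding** — documents serialize to a
  left-to-right event string such as

  ```
  Living_Alone [Vit seul] ; Tobacco [Tabac] Status=past [sevré] History [il y a 8 ans]
  ```

  and generated strings are parsed back and *grounded* to character
  offsets: triggers take the leftmost unconsumed occurrence of their
  text, arguments the occurrence nearest their trigger, with case- and
  diacritic-folded fallbacks for tokenizer-corrupted surfaces.
* **Two-level evaluation** — level 1 scores per-document presence of
  labeled findings (e.g. `Housing_No`, `Tobacco_StatusTime:current`);
  level 2 scores extraction as a slot-filling task over every trigger and
  (trigger, relation) key with macro P/R/F1, under *exact*
  (identical offsets) and *overlap* (≥ 1 shared character) span criteria,
  with F1 = 2PR/(P+R) per key and unweighted macro averaging.
* **Inter-annotator agreement** — pairwise micro-pooled entity and
  relation F-measures.
* **Synthetic gold corpus** — a seeded template generator of realistic
  French social-history sections with exact annotations, so every
  pipeline stage is testable without any hospital data.
* **Structured-vs-note comparison** — per-patient completeness against
  mapped ICD-10 Z-codes, and section-coverage accounting of what a
  section-restricted pipeline misses.

The extraction model itself (a fine-tuned encoder-decoder such as
Flan-T5) is deliberately a pluggable backend: the package ships the
training-pair builder, the serialization dialect, the grounding rules and
the scorers, plus an oracle and a keyword baseline for testing.

## Worked example

```python
from sdohfr import (SynthConfig, generate_corpus, serialize_document,
                    parse_sequence, ground_events, score_level2)

corpus = generate_corpus(SynthConfig(n_docs=10, seed=42))
doc = corpus[0]
print(doc.text)
# Contexte social :
# Mariée. Ne consomme pas d’alcool. Pas d’aides à domicile. Tabac sevré,
# 20 paquets de cigarettes. Vit seule. Courtier dans le textile.

print(serialize_document(doc))
# MaritalStatus_InRelationship [Mariée] ; Alcohol [alcool] Status=none
# [Ne consomme pas] ; Housing_Yes [Pas d’aides à domicile] ; Tobacco [Tabac]
# Status=past [sevré] Amount [20 paquets de cigarettes] ; Living_Alone
# [Vit seule] ; Job [Courtier dans le textile]

events, diags = parse_sequence(serialize_document(doc))
grounded, _ = ground_events(events, doc.text, doc.doc_id)
report = score_level2(corpus, corpus, "overlap")
print(report.overall.f1)   # 1.0 — self-score perfection
```

The serialized string is the seq2seq target: events ordered by trigger
offset, each trigger followed by its argument slots, with the Status
value inlined.  Grounding the parsed string recovers every original span,
and scoring a corpus against itself yields macro F1 = 1.0 at both levels
and under both criteria.

Each script in `examples/` demonstrates one capability (corpus
generation, linearization + grounding, baseline evaluation, agreement,
section coverage, Z-code completeness) and prints the numbers it
computes.  A thin CLI mirrors the library:

```bash
sdoh synth --seed 3 --n-docs 6 --out corpus/
sdoh validate corpus/
sdoh evaluate --level 2 --criterion overlap --gold corpus/ --pred corpus/
```

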