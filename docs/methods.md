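# Methods

This note documents the models, rules and numerical choices behind
`sdohfr`, and what its synthetic test conditions do and do not show about
real clinical data.

## Annotation scheme

The scheme describes social determinants of health (SDoH) in French
clinical notes with 25 entity labels grouped into 13 categories (living
condition, marital status, descendants, employment status, job, tobacco,
alcohol, drug, housing, education, physical activity, income,
ethnicity/country of birth) plus six argument labels (StatusTime,
History, Duration, Amount, Frequency, Type).  Seventeen labels carry
their category value in the label itself (e.g. `Housing_No`); the others
(Job, Last_job, Income, Education, Ethnicity and the three substances)
are bare text spans.  Substance use follows an event design: only the
trigger span is annotated, and the consumption status lives as a
`current | past | none` attribute on a StatusTime mention linked by a
`Status` relation.

Relation legality is a closed triple table: `Status` for the three
substances; `Amount` for substances and `Descendants_Yes`; `Duration` for
substances; `Frequency` for substances and both physical-activity labels;
`Type` for substances and `Descendants_Yes`; `History` for any SDoH head.
Design choices that were genuinely open:

* **Required relations.** Only `Status` on a substance trigger is
  *required* — a substance mention without its status is not a complete
  event, and the level-1 finding (`Tobacco_StatusTime:past`) cannot be
  formed without it.  All other relations are optional.
* **Frequency** is legal for both `PhysicalActivity_Yes` and
  `PhysicalActivity_No` (a patient may be described as exercising rarely).
* **Job / Last_job** may annotate overlapping or nested spans of the same
  text; both map to the category *job*.
* **Offsets** are counted in Unicode code points over NFC-normalized
  text, 0-based half-open — the BRAT convention.  Diacritic folding is
  used for matching only, never for offsets.
* **Ethnicity** stays in the scheme as a label (documented in French
  notes as country of birth); deployments subject to stricter data
  -protection constraints can simply not emit it.
* An argument mention attached to no relation cannot head an event and is
  therefore invisible to the serializer; the generator never produces
  one, and standoff IO still round-trips it.

## Linearization dialect

A document serializes to events joined by `" ; "`; an event is
`LABEL [trigger_text]` followed by argument slots `REL [text]`, with
`Status=value` carrying the status inline.  `[`, `]`, `;` and `\` inside
text are backslash-escaped.  Events are ordered by trigger start (ties:
label lexicographic), arguments by span start.  This concrete grammar is
the package's single normative dialect: unambiguous, escapable and
round-trippable (`parse_sequence ∘ serialize_document` is the identity on
events, property-tested over seeded corpora).  Text is kept verbatim —
no ASCII folding — so accented surfaces survive serialization; fuzzy
recovery is grounding's job.  Parsing never raises on model output:
malformed segments and illegal or unknown argument slots become
diagnostics, mirroring how generation models actually fail (format
drift, invented labels, bad status values).

Training pairs for a seq2seq backbone are (raw section text, target
sequence) with no prompt prefix; the fine-tuning configuration
(`FinetuneConfig`, default 10 epochs on `google/flan-t5-large`) is
recorded as plain data and no deep-learning framework is imported — the
backbone is a pluggable backend behind the `Predictor` contract.

## Grounding rules

Generated sequences carry no offsets, so events are grounded greedily:

* **Triggers**, in sequence order, take the leftmost occurrence of their
  text whose exact span has not been consumed by an earlier trigger;
  distinct triggers therefore never share a span.  "Consumed" applies to
  triggers only — arguments may reuse spans, since quantities like "20"
  legitimately repeat.
* **Arguments** take the occurrence whose midpoint is nearest (absolute
  character distance) to the grounded trigger's midpoint, ties leftmost.
* Matching escalates exact → case-insensitive → diacritic-folded; the
  folded level recovers accents corrupted by English-centric tokenizers
  (e.g. a generated `cocaine` grounds onto `cocaïne`).  A surface whose
  letters were dropped outright (e.g. `cocane`) remains unrecoverable and
  is dropped with a `no-match` diagnostic.
* A substance event whose Status argument cannot be grounded is dropped
  entirely so the output document always passes schema validation.

Grounding is character-level and deliberately greedy — no global
minimum-displacement assignment.  When every surface occurs once the
rules trivially recover the unique spans; when surfaces repeat in the
same order as the gold annotations (which the corpus generator
guarantees for itself), they are exact; on adversarial text the greedy
choice can misplace a span, which is an inherent property of
leftmost/nearest post-processing and is surfaced through
`ambiguous-resolved` diagnostics rather than hidden.

## Evaluation

**Level 1** measures per-document *presence* of labeled findings: the 17
category-valued labels plus nine substance composites
(`<substance>_StatusTime:<value>`), 26 possible finding labels; span-only
labels do not participate.  Presence is binary per document (not
instance-counted), and macro averaging runs over finding labels with any
activity.

**Level 2** scores slot filling over 69 evaluation keys: 25 trigger keys
and 44 legal (label, relation) keys.  Scoring is two-stage: triggers are
matched 1-to-1 within each label, then arguments are matched per relation
type *within each matched trigger pair*; Status arguments additionally
require equal status values.  Arguments of unmatched triggers count as
false positives (prediction side) or false negatives (gold side).  Both
the joint-event reading (an event matches when its trigger and its slots
match) and per-pair reporting fall out of this n2c2-style two-stage
procedure.

Span equivalence has two criteria — `exact` (identical offsets) and
`overlap` (at least one shared character) — and per-key F1 under overlap
is never below exact, a property the suite checks on hundreds of
boundary-perturbed corpora.

Numerical conventions: precision (recall) is 0 when its denominator is 0
while the other count is positive; a key with `tp = fp = fn = 0` is
excluded from every average; macro scores are unweighted means of per-key
precision, recall and F1; per-category scores average the keys whose head
label belongs to the category.  Matching processes spans in ascending
end-then-start order and takes the earliest-ending compatible unmatched
gold span: for interval overlap (and a fortiori exact equality) this
greedy *is* a maximum matching — a start-ordered greedy is not, on nested
spans — so the scorer never penalizes matching-order artifacts; the suite
verifies equality with an exhaustive maximum-matching oracle on all
instances up to 6×6.

**Inter-annotator agreement** pools counts over documents (micro), with
an entity match requiring identical label and span, and a relation match
identical type, head and argument (plus equal Status value).
F = 2tp/(2tp+fp+fn) is symmetric in the annotators.  Two empty sets carry
no evidence of disagreement and score 1.0 with an explicit flag; more
than two annotators aggregate as the unweighted mean over unordered
pairs.  On trigger-only documents entity agreement coincides with the
micro-pooled exact trigger stage of the level-2 scorer (cross-checked in
the suite).

## Synthetic corpus

The generator emulates short French social-history sections: a header
("Mode de vie :" …) followed by 1–8 telegraphic sentences, one per
included SDoH category, realized from a template bank seeded with the
scheme's canonical example surfaces.  Default conditions: 340 documents
per corpus (the size of a realistic held-out test set); per-category
inclusion probabilities skewed toward the categories that dominate real
corpora (living condition 0.75, marital status 0.70, descendants 0.65,
tobacco 0.60, job 0.55, alcohol 0.55 … income 0.06, education 0.07);
substance status distributed 0.45/0.35/0.20 over current/past/none;
optional argument slots (amount 0.55, frequency 0.40, type 0.35,
history 0.35, duration 0.30).  Within a category, label choice is
weighted toward the empirically frequent labels (e.g.
`MaritalStatus_InRelationship`, `Descendants_Yes`, `Housing_Yes`).
Generation is pure-template and fully deterministic given the seed.

Template surfaces are arranged so that every trigger's gold occurrence is
its leftmost unconsumed exact match and every argument's gold occurrence
is the nearest to its trigger; repeated surfaces across sentences (the
digit "0" against "20"/"30"/"2011", duplicate status words across
substances in earlier drafts) are kept only where the nearest-occurrence
rule still resolves them, so grounding round-trips are exact by
construction — the suite verifies this over thousands of seeded
documents.

What passing on this corpus shows: the scheme, IO, serialization,
grounding and scoring machinery are lossless and self-consistent under
realistic surface statistics, including mild grounding ambiguity.  What
it does not show: performance on real notes — real clinical text has
typos, broken section structure, long-range anaphora, surface variation
far beyond a template bank, and annotation disagreement.  No claim about
real-data extraction quality follows from green tests here.

## Structured-vs-note comparison

Z-codes normalize dot-insensitively (`Z60.2 ≡ Z602`).  The shipped
default Z-code → category map is explicitly provisional; real use
requires a site-specific, clinician-reviewed mapping.  A patient counts
as documented in notes with ≥ 1 annotated category, in structured data
with ≥ 1 mapped Z-code, and as overlapping when the two category sets
intersect.  For section coverage, "inside" requires full containment of
the annotation span in a section span (straddling spans count as
outside, conservatively); an outside annotation in a sectioned document
is redundant iff its category also occurs inside that document's
section, and the missed-unique count is
`outside-in-sectionless-documents + (outside-in-sectioned − redundant)`.
Percentages are rounded half-up to one decimal.

## Section extraction

A configurable header lexicon (default: "mode de vie", "habitus",
"contexte social", "situation sociale", "conditions de vie") is matched
case- and diacritic-insensitively at line starts, with an optional
trailing colon; the body runs from after the header (same line if
content follows the colon) to the next header-like line — at most 60
characters ending in `:` or fully upper-case — or the end of the note.
Bodies never overlap.  Production header inventories are site-specific,
which is why the lexicon is configuration rather than code.

## Problem sizes in the test suite

The default suite generates corpora of tens to a few thousand documents
per property (1 000 for round-trip identity, 500 two-document corpora for
criterion monotonicity, 2 000 for distribution checks, ≤ 6×6 instances
for exhaustive matching oracles) and completes in a few seconds on one
CPU; all fixtures are generated in memory at test time.

## Known limitations

* The lexicon baseline is intentionally naive (global cue search, no
  windowing); it exists to exercise the pipeline, not to be competitive.
* Grounding is greedy; pathological repetition can misplace spans, and
  only diagnostics (not global optimization) expose it.
* Level-1 aggregation is macro over finding labels; corpora where
  per-document micro-averaging matters need their own aggregation.
* The default Z-code map is a placeholder; completeness results are only
  as good as the supplied mapping.
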