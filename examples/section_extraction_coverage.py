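"""Extract the social-history section of a full note and measure coverage.

Applies the rule-based header-lexicon extractor to a full clinical note,
then quantifies how many SDoH annotations a section-restricted pipeline
would see versus miss.
"""
from sdohfr import CoverageAnnotation, Span, extract_social_history, section_coverage

NOTE = (
    "COMPTE RENDU DE CONSULTATION\n"
    "Motif : dyspnée.\n"
    "Mode de vie : Vit seule. Tabac sevré il y a 8 ans.\n"
    "Antécédents :\n"
    "BPCO. Ethylisme chronique.\n"
    "CONCLUSION\n"
    "Poursuite du sevrage.\n"
)

sections = extract_social_history(NOTE)
for sec in sections:
    body = NOTE[sec.body_span.start:sec.body_span.end]
    print(f"section under header {sec.header!r}: {body!r} "
          f"at ({sec.body_span.start}, {sec.body_span.end})")

# Annotations of the full note: two inside the section, one (alcohol)
# in the antecedents — redundant only if alcohol also appeared inside.
def span_of(surface: str) -> Span:
    start = NOTE.index(surface)
    return Span(start, start + len(surface))

annotations = [
    CoverageAnnotation("note", span_of("Vit seule"), "living condition"),
    CoverageAnnotation("note", span_of("Tabac"), "tobacco"),
    CoverageAnnotation("note", span_of("Ethylisme"), "alcohol"),
]
report = section_coverage(["note"], {"note": [s.body_span for s in sections]}, annotations)
print(f"\n{report.inside}/{report.total} annotations inside the section "
      f"({report.pct_inside}%)")
print(f"missed unique if restricted to the section: {report.missed_unique} "
      f"({report.pct_missed_unique}%)")
# The alcohol mention lives outside the social-history section and its
# category is not documented inside, so restricting inference to the
# section would lose it.
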