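"""Unicode helpers: offset-preserving case/diacritic folding and substring search.

Offsets throughout the toolkit are counted in Unicode code points over
NFC-normalized text (0-based, half-open), matching the BRAT convention.
Folding is used for *matching only*; reported spans always index the
original text.
"""
from __future__ import annotations

import unicodedata

from .schema import Span


def nfc(text: str) -> str:
    return unicodedata.normalize("NFC", text)


def fold_with_map(
    s: str, *, lower: bool = False, strip_marks: bool = False
) -> tuple[str, list[int]]:
    """Fold ``s`` and return (folded, index_map).

    ``index_map[j]`` is the index in ``s`` of the character that produced
    folded character ``j``.  A source character may expand to several folded
    characters (casefolding, canonical decomposition) or to none (a lone
    combining mark under ``strip_marks``).
    """
    out: list[str] = []
    idx: list[int] = []
    for i, ch in enumerate(s):
        if strip_marks:
            chars = [c for c in unicodedata.normalize("NFD", ch) if not unicodedata.combining(c)]
        else:
            chars = [ch]
        if lower:
            chars = [c2 for c in chars for c2 in c.casefold()]
        for c in chars:
            out.append(c)
            idx.append(i)
    return "".join(out), idx


def _find_all(needle: str, hay: str) -> list[int]:
    starts = []
    pos = hay.find(needle)
    while pos != -1:
        starts.append(pos)
        pos = hay.find(needle, pos + 1)
    return starts


def occurrences(needle: str, text: str) -> tuple[list[Span], int]:
    """All spans of ``needle`` in ``text`` with a fold-level escalation.

    Levels: 0 exact substring, 1 case-insensitive, 2 case- and
    diacritic-insensitive (recovers tokenizer-corrupted accents such as
    "cocane" for "cocaïne").  The first level with at least one hit wins.
    Returns ``([], 0)`` when the needle is empty or absent at every level.
    """
    if not needle:
        return [], 0
    hits = [Span(p, p + len(needle)) for p in _find_all(needle, text)]
    if hits:
        return hits, 0
    for level, kw in ((1, {"lower": True}), (2, {"lower": True, "strip_marks": True})):
        f_needle, _ = fold_with_map(needle, **kw)
        if not f_needle:
            continue
        f_text, idx = fold_with_map(text, **kw)
        spans = []
        for p in _find_all(f_needle, f_text):
            start = idx[p]
            end = idx[p + len(f_needle) - 1] + 1
            if start < end:
                spans.append(Span(start, end))
        if spans:
            # folding may collapse distinct source ranges onto one span
            uniq = sorted(set(spans), key=lambda s: (s.start, s.end))
            return uniq, level
    return [], 0
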