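"""Rule-based extraction of the social-history section from a full clinical note.

French clinical notes are semi-structured: short header lines ("Mode de
vie :", "Antécédents :", ALL-CAPS headings) open named sections.  The
extractor matches a configurable header lexicon case- and
diacritic-insensitively at line starts and returns the body span of each
social-history section, ending at the next header-like line or at the end
of the note.  Diacritic folding is used for matching only; reported offsets
always index the original text.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._text import fold_with_map, nfc
from .errors import ConfigError
from .schema import Span

#: Default header lexicon; the set of headers used in production notes is
#: site-specific, so this is configuration, not code.
DEFAULT_HEADER_LEXICON: tuple[str, ...] = (
    "mode de vie",
    "habitus",
    "contexte social",
    "situation sociale",
    "conditions de vie",
)

#: A line is header-like when it is short and looks like a heading.
_MAX_HEADER_LEN = 60


@dataclass(frozen=True)
class SectionSpan:
    """A matched social-history section: header string and body span."""

    header: str
    body_span: Span


def _fold(s: str) -> str:
    folded, _ = fold_with_map(s, lower=True, strip_marks=True)
    return folded


def _is_header_like(stripped: str) -> bool:
    if not stripped or len(stripped) > _MAX_HEADER_LEN:
        return False
    if stripped.endswith(":"):
        return True
    return any(c.isalpha() for c in stripped) and stripped == stripped.upper()


def _match_lexicon_header(line: str, folded_lexicon: list[str]) -> tuple[int, str] | None:
    """If ``line`` starts with a lexicon header, return (body_offset, header).

    ``body_offset`` is the in-line offset where the body starts (after the
    header words, optional spaces and one optional colon); ``header`` is
    the matched header as written in the line.
    """
    stripped_lead = len(line) - len(line.lstrip())
    f_stripped, f_idx = fold_with_map(line.lstrip(), lower=True, strip_marks=True)
    for entry in folded_lexicon:
        if not f_stripped.startswith(entry):
            continue
        rest = f_stripped[len(entry):]
        # header word must end here: next folded char is a boundary
        if rest and rest[0].isalnum():
            continue
        # position in the original (unstripped) line just past the header
        if len(entry) < len(f_idx):
            pos = stripped_lead + f_idx[len(entry)]
        else:
            pos = len(line)
        header = line[stripped_lead:pos].rstrip()
        while pos < len(line) and line[pos] in " \t":
            pos += 1
        if pos < len(line) and line[pos] == ":":
            pos += 1
        while pos < len(line) and line[pos] in " \t":
            pos += 1
        return pos, header
    return None


def extract_social_history(
    note_text: str,
    header_lexicon: tuple[str, ...] | list[str] = DEFAULT_HEADER_LEXICON,
) -> list[SectionSpan]:
    """All social-history sections of a note, in order of position.

    A section opens after a line starting with a lexicon header (matched
    case/diacritic-insensitively, optional trailing colon; content on the
    header line after the colon belongs to the body) and closes at the next
    header-like line — a stripped line of at most 60 characters that ends in
    ``:`` or is fully upper-case — or at the end of the note.  Empty bodies
    are discarded; bodies never overlap.
    """
    if not header_lexicon:
        raise ConfigError("header lexicon is empty")
    text = nfc(note_text)
    folded_lexicon = sorted((_fold(h.strip()) for h in header_lexicon), key=len, reverse=True)
    if any(not h for h in folded_lexicon):
        raise ConfigError("header lexicon contains an empty entry")

    sections: list[SectionSpan] = []
    open_header: str | None = None
    open_start = 0

    def close(at: int) -> None:
        nonlocal open_header
        if open_header is None:
            return
        start, end = open_start, at
        while start < end and text[start] in " \t\r\n":
            start += 1
        while end > start and text[end - 1] in " \t\r\n":
            end -= 1
        if end > start:
            sections.append(SectionSpan(open_header, Span(start, end)))
        open_header = None

    pos = 0
    for raw in text.splitlines(keepends=True):
        line = raw.rstrip("\r\n")
        match = _match_lexicon_header(line, folded_lexicon)
        if match is not None:
            body_off, header = match
            close(pos)
            open_header = header
            if body_off < len(line):
                open_start = pos + body_off
            else:
                open_start = pos + len(raw)  # body starts on the next line
        elif open_header is not None and _is_header_like(line.strip()):
            close(pos)
        pos += len(raw)
    close(len(text))
    return sections
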