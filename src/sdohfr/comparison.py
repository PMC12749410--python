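"""Structured-vs-unstructured SDoH documentation comparison.

Two complementary analyses:

* **Patient completeness** — how many patients have at least one SDoH
  category documented in their note annotations versus in their coded
  ICD-10 Z-codes (Z00–Z99 "factors influencing health status"), given a
  Z-code → SDoH-category map.  Structured Z-coding is known to capture
  only a small fraction of what clinicians write in free text.
* **Section coverage** — how many annotations fall inside the extracted
  social-history section versus elsewhere in the note, and how much
  *unique* information a section-restricted pipeline misses: annotations
  in documents without any section, plus outside-section annotations whose
  category is not already mentioned inside the section of the same
  document.

All percentages are rounded half-up to one decimal, matching how such
counts are conventionally reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, ConfigError, IntegrityError
from .schema import CATEGORIES, Span


def round_pct(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal; 0.0 when total is 0."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


# --------------------------------------------------------------------------- #
# Z-codes


def normalize_zcode(code: str) -> str:
    """Dot- and case-insensitive Z-code normal form (Z60.2 ≡ Z602)."""
    return code.strip().upper().replace(".", "").replace(" ", "")


#: Small provisional default map; any real deployment must supply the
#: site-specific mapping reviewed by a clinician.
DEFAULT_ZCODE_MAP: dict[str, str] = {
    "Z290": "living condition",
    "Z6020": "living condition",
    "Z602": "living condition",
    "Z590": "housing",
    "Z591": "housing",
    "Z595": "income",
    "Z596": "income",
    "Z560": "employment status",
    "Z630": "marital status",
    "Z635": "marital status",
    "Z550": "education",
    "Z720": "tobacco",
    "Z714": "alcohol",
    "Z715": "drug",
}


def load_zcode_map(
    table: str | Path | pd.DataFrame | Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Load a two-column (code, category) table into a normalized map.

    Accepts a delimited file path (separator sniffed by pandas), a
    DataFrame, or an iterable of pairs.  Unknown categories and
    conflicting duplicate codes are configuration errors; identical
    duplicates collapse.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep=None, engine="python", header=None,
                         names=["code", "category"], comment="#",
                         skip_blank_lines=True, dtype=str)
        pairs = list(df.itertuples(index=False, name=None))
    elif isinstance(table, pd.DataFrame):
        pairs = [tuple(row[:2]) for row in table.itertuples(index=False, name=None)]
    else:
        pairs = [tuple(p) for p in table]
    out: dict[str, str] = {}
    for code, category in pairs:
        code_n = normalize_zcode(str(code))
        category = str(category).strip()
        if not code_n.startswith("Z"):
            raise ConfigError(f"not a Z-code: {code!r}")
        if category not in CATEGORIES:
            raise ConfigError(f"unknown SDoH category {category!r} for code {code}")
        if code_n in out and out[code_n] != category:
            raise ConfigError(
                f"conflicting categories for code {code}: {out[code_n]!r} vs {category!r}")
        out[code_n] = category
    return out


@dataclass(frozen=True)
class CompletenessReport:
    """Patients with any SDoH documentation, per source and overlapping."""

    n_patients: int
    n_with_note_sdoh: int
    n_with_zcode_sdoh: int
    n_overlap: int
    pct_note: float
    pct_zcode: float
    pct_overlap: float

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_with_note_sdoh": self.n_with_note_sdoh,
            "n_with_zcode_sdoh": self.n_with_zcode_sdoh,
            "n_overlap": self.n_overlap,
            "pct_note": self.pct_note,
            "pct_zcode": self.pct_zcode,
            "pct_overlap": self.pct_overlap,
        }


def patient_completeness(
    note_categories_by_patient: Mapping[str, Iterable[str]],
    zcodes_by_patient: Mapping[str, Iterable[str]],
    zmap: Mapping[str, str] | None = None,
) -> CompletenessReport:
    """Compare per-patient SDoH documentation between notes and Z-codes.

    A patient counts for notes when at least one annotated category is
    present, for structured data when at least one Z-code maps through
    ``zmap``; the overlap requires the two category sets to intersect.
    Invariant to patient ordering and duplicate Z-codes.
    """
    zmap = DEFAULT_ZCODE_MAP if zmap is None else zmap
    if set(note_categories_by_patient) != set(zcodes_by_patient):
        raise AlignmentError("note and Z-code inputs cover different patients")
    patients = sorted(note_categories_by_patient)
    if not patients:
        raise AlignmentError("empty patient universe")
    n_note = n_z = n_overlap = 0
    for pid in patients:
        note_cats = {c for c in note_categories_by_patient[pid]}
        for c in note_cats:
            if c not in CATEGORIES:
                raise ConfigError(f"unknown SDoH category {c!r} for patient {pid}")
        z_cats = {
            zmap[normalize_zcode(code)]
            for code in zcodes_by_patient[pid]
            if normalize_zcode(code) in zmap
        }
        if note_cats:
            n_note += 1
        if z_cats:
            n_z += 1
        if note_cats and z_cats and (note_cats & z_cats):
            n_overlap += 1
    n = len(patients)
    return CompletenessReport(
        n, n_note, n_z, n_overlap,
        round_pct(n_note, n), round_pct(n_z, n), round_pct(n_overlap, n),
    )


# --------------------------------------------------------------------------- #
# Section coverage


@dataclass(frozen=True)
class CoverageAnnotation:
    """One SDoH annotation located in a note: (document, span, category)."""

    doc_id: str
    span: Span
    category: str


@dataclass(frozen=True)
class CoverageReport:
    """Where annotations sit relative to the social-history section."""

    total: int
    inside: int
    outside: int
    outside_no_section: int
    outside_with_section: int
    outside_redundant: int
    missed_unique: int
    pct_inside: float
    pct_outside: float
    pct_missed_unique: float

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "inside": self.inside,
            "outside": self.outside,
            "outside_no_section": self.outside_no_section,
            "outside_with_section": self.outside_with_section,
            "outside_redundant": self.outside_redundant,
            "missed_unique": self.missed_unique,
            "pct_inside": self.pct_inside,
            "pct_outside": self.pct_outside,
            "pct_missed_unique": self.pct_missed_unique,
        }


def section_coverage(
    doc_ids: Iterable[str],
    section_spans: Mapping[str, Sequence[Span]],
    annotations: Sequence[CoverageAnnotation],
) -> CoverageReport:
    """Quantify what a section-restricted pipeline would miss.

    An annotation is *inside* iff its span is fully contained in a section
    span of its document (a straddling span counts as outside,
    conservatively).  An outside annotation in a sectioned document is
    *redundant* iff its category also occurs inside that document's
    section.  ``missed_unique`` = annotations in section-less documents +
    non-redundant outside annotations in sectioned documents.
    """
    universe = set(doc_ids)
    for ann in annotations:
        if ann.doc_id not in universe:
            raise IntegrityError(f"annotation references unknown document {ann.doc_id!r}")

    def is_inside(ann: CoverageAnnotation) -> bool:
        return any(sec.contains(ann.span) for sec in section_spans.get(ann.doc_id, ()))

    inside_cats: dict[str, set[str]] = {}
    for ann in annotations:
        if is_inside(ann):
            inside_cats.setdefault(ann.doc_id, set()).add(ann.category)

    total = len(annotations)
    inside = outside_no_section = outside_with_section = outside_redundant = 0
    for ann in annotations:
        if is_inside(ann):
            inside += 1
        elif not section_spans.get(ann.doc_id):
            outside_no_section += 1
        else:
            outside_with_section += 1
            if ann.category in inside_cats.get(ann.doc_id, set()):
                outside_redundant += 1
    outside = outside_no_section + outside_with_section
    missed_unique = outside_no_section + (outside_with_section - outside_redundant)
    return CoverageReport(
        total, inside, outside,
        outside_no_section, outside_with_section, outside_redundant, missed_unique,
        round_pct(inside, total), round_pct(outside, total),
        round_pct(missed_unique, total),
    )
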