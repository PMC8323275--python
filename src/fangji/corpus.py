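"""Domain types and file I/O for formula corpora.

A *formula* (方剂) is a multi-herb prescription: a set of decoction pieces,
each with a dose, plus bibliographic metadata (source book, formation year,
department, efficacy tags, nature/flavor/meridian tags).  Corpora are stored
as JSON lines, one formula per line, UTF-8.  Term dictionaries and dose-unit
conversion tables are tab-separated text with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field, field_validator

from .errors import CorpusParseError, DictionaryError, DuplicateIdError

#: Semantic types recognized in classical formula text, as used for term
#: dictionaries and segmentation.  "unknown" is reserved for out-of-dictionary
#: single characters and is not a valid dictionary entry type.
SEMANTIC_TYPES = frozenset(
    {
        "physiology",
        "symptom",
        "syndrome",
        "pathological factors",
        "pathological products",
        "efficacy",
        "method of treatment",
        "channel meridian and acupuncture points",
        "four diagnostic methods",
        "traditional Chinese drug",
        "prescription",
        "nature and flavor",
        "toxicity",
        "processing",
        "contraindications",
        "decoction method",
        "proprietary words",
    }
)

#: Plausible range for formation years (signed, negative = BCE), half-open.
DEFAULT_YEAR_RANGE = (-2000, 2100)


class Dose(BaseModel):
    """A dose as written plus its normalized mass in grams.

    ``grams`` is ``None`` when ``raw_unit`` was absent from the active unit
    table; such doses are *unresolved* and excluded from dose-based features.
    """

    raw_value: float = Field(ge=0)
    raw_unit: str
    grams: Optional[float] = Field(default=None, ge=0)

    @property
    def resolved(self) -> bool:
        return self.grams is not None


class PieceUse(BaseModel):
    """One decoction piece within a formula's composition."""

    raw_name: str
    canonical_name: str = Field(min_length=1)
    dose: Optional[Dose] = None
    processing_note: Optional[str] = None


class FormulaRecord(BaseModel):
    """One formula with metadata, tags, and composition."""

    formula_id: int
    name: str
    source_book: str = ""
    formation_year: Optional[int] = None
    dynasty: str = ""
    department: str = ""
    efficacy_tags: list[str] = Field(default_factory=list)
    nature_flavor_meridian: list[str] = Field(default_factory=list)
    composition: list[PieceUse] = Field(min_length=1)
    original_text: str = ""

    @field_validator("formation_year")
    @classmethod
    def _plausible_year(cls, v: Optional[int]) -> Optional[int]:
        lo, hi = DEFAULT_YEAR_RANGE
        if v is not None and not (lo <= v < hi):
            raise ValueError(f"formation_year {v} outside plausible range [{lo}, {hi})")
        return v


class TermDictionary:
    """Raw term -> (canonical term, semantic type) mapping.

    Every canonical term maps to itself, so lookups are idempotent.  Semantic
    types are restricted to :data:`SEMANTIC_TYPES`.
    """

    def __init__(self, entries: dict[str, tuple[str, str]] | None = None):
        self.entries: dict[str, tuple[str, str]] = {}
        self._syn_cache: dict[str, set[str]] | None = None
        if entries:
            for raw, (canonical, stype) in entries.items():
                self.add(raw, canonical, stype)

    def add(self, raw: str, canonical: str, semantic_type: str) -> None:
        if semantic_type not in SEMANTIC_TYPES:
            raise DictionaryError(f"unknown semantic type {semantic_type!r} for {raw!r}")
        self.entries[raw] = (canonical, semantic_type)
        self._syn_cache = None
        # keep the canonical-identity invariant
        if canonical not in self.entries:
            self.entries[canonical] = (canonical, semantic_type)

    def lookup(self, raw: str) -> Optional[tuple[str, str]]:
        return self.entries.get(raw)

    def canonical(self, raw: str) -> tuple[str, bool]:
        """Canonical form of ``raw`` and whether the dictionary matched."""
        hit = self.entries.get(raw)
        if hit is None:
            return raw, False
        return hit[0], True

    def synonyms(self, canonical: str) -> set[str]:
        """All raw surface forms (including itself) mapping to ``canonical``."""
        if self._syn_cache is None:
            cache: dict[str, set[str]] = {}
            for raw, (canon, _) in self.entries.items():
                cache.setdefault(canon, set()).add(raw)
            self._syn_cache = cache
        return set(self._syn_cache.get(canonical, ()))

    def terms(self) -> Iterable[str]:
        return self.entries.keys()

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, raw: str) -> bool:
        return raw in self.entries


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O


def _piece_to_obj(p: PieceUse) -> dict:
    return {
        "raw_name": p.raw_name,
        "canonical_name": p.canonical_name,
        "dose_value": p.dose.raw_value if p.dose else None,
        "dose_unit": p.dose.raw_unit if p.dose else None,
        "dose_grams": p.dose.grams if p.dose else None,
        "processing_note": p.processing_note,
    }


def _piece_from_obj(obj: dict) -> PieceUse:
    dose = None
    if obj.get("dose_value") is not None:
        dose = Dose(
            raw_value=obj["dose_value"],
            raw_unit=obj.get("dose_unit") or "",
            grams=obj.get("dose_grams"),
        )
    return PieceUse(
        raw_name=obj["raw_name"],
        canonical_name=obj["canonical_name"],
        dose=dose,
        processing_note=obj.get("processing_note"),
    )


def record_to_obj(rec: FormulaRecord) -> dict:
    obj = rec.model_dump(exclude={"composition"})
    obj["composition"] = [_piece_to_obj(p) for p in rec.composition]
    return obj


def record_from_obj(obj: dict) -> FormulaRecord:
    comp = [_piece_from_obj(p) for p in obj.get("composition", [])]
    fields = {k: v for k, v in obj.items() if k != "composition"}
    return FormulaRecord(composition=comp, **fields)


def load_corpus(path: str | Path) -> list[FormulaRecord]:
    """Load a JSON-lines corpus, validating every record.

    Raises :class:`CorpusParseError` (naming the line) on malformed input and
    :class:`DuplicateIdError` when two records share a formula_id.
    """
    records: list[FormulaRecord] = []
    seen: set[int] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                rec = record_from_obj(obj)
            except DuplicateIdError:
                raise
            except Exception as exc:  # json or pydantic failure
                raise CorpusParseError(line_no, str(exc)) from exc
            if rec.formula_id in seen:
                raise DuplicateIdError(
                    f"duplicate formula_id {rec.formula_id} at line {line_no}"
                )
            seen.add(rec.formula_id)
            records.append(rec)
    return records


def save_corpus(records: list[FormulaRecord], path: str | Path) -> None:
    """Write a corpus as JSON lines; lossless inverse of :func:`load_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_obj(rec), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Dictionary and unit-table I/O


def load_dictionary(path: str | Path) -> TermDictionary:
    """Load a TSV term dictionary with columns raw, canonical, semantic_type."""
    d = TermDictionary()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["raw", "canonical", "semantic_type"]:
            raise DictionaryError(
                f"expected header raw/canonical/semantic_type, got {header!r}"
            )
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DictionaryError(f"row {row_no}: expected 3 columns, got {len(parts)}")
            raw, canonical, stype = parts[0], parts[1], parts[2]
            try:
                d.add(raw, canonical, stype)
            except DictionaryError as exc:
                raise DictionaryError(f"row {row_no}: {exc}") from exc
    return d


def load_unit_table(path: str | Path) -> dict[str, float]:
    """Load a TSV unit table with columns unit, grams (grams per one unit)."""
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["unit", "grams"]:
            raise DictionaryError(f"expected header unit/grams, got {header!r}")
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DictionaryError(f"row {row_no}: expected 2 columns")
            try:
                factor = float(parts[1])
            except ValueError as exc:
                raise DictionaryError(f"row {row_no}: bad factor {parts[1]!r}") from exc
            if factor <= 0:
                raise DictionaryError(f"row {row_no}: factor must be positive")
            table[parts[0]] = factor
    return table


def default_unit_table() -> dict[str, float]:
    """Built-in dose-unit conversion table (grams per unit).

    Historical units (两, 钱, 分, 厘, 斤) use the late-imperial apothecary
    convention of 1 两 = 37.3 g; these factors varied by dynasty, so serious
    work should supply a period-appropriate table via :func:`load_unit_table`.
    """
    return {
        "g": 1.0,
        "克": 1.0,
        "kg": 1000.0,
        "mg": 0.001,
        "两": 37.3,
        "钱": 3.73,
        "分": 0.373,
        "厘": 0.0373,
        "斤": 596.8,
    }
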