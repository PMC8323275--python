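"""Deterministic extraction and standardization of formula text.

Classical formula records arrive as semi-structured text.  This module
segments text against a term dictionary (forward maximum matching: at each
position the longest dictionary term wins, unmatched characters become
single-character tokens of type ``"unknown"``), normalizes raw terms to their
canonical dictionary form, converts doses to grams through a unit table, and
parses whole text blocks into validated :class:`~fangji.corpus.FormulaRecord`
objects.

The block dialect understood by :func:`extract_formula` is the one emitted by
:func:`fangji.synthetic.render_blocks`: labeled lines ``【field】value``, with
the composition as ``name value unit（note）`` entries joined by ``；``.  It is
a convenience exchange format, not an archival standard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .corpus import Dose, FormulaRecord, PieceUse, TermDictionary
from .errors import ExtractionError


@dataclass(frozen=True)
class Token:
    """A segmented span: surface slice, canonical form, semantic type, offsets.

    Offsets are 0-based, half-open; ``surface == text[span[0]:span[1]]``.
    """

    surface: str
    canonical: str
    semantic_type: str
    span: tuple[int, int]


def segment_text(text: str, dictionary: TermDictionary) -> list[Token]:
    """Tile ``text`` into tokens by forward maximum matching.

    Total function: every character lands in exactly one token, so the
    concatenated surfaces reconstruct the input.
    """
    if not text:
        return []
    max_len = max((len(t) for t in dictionary.terms()), default=1)
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        match = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = text[i : i + length]
            hit = dictionary.lookup(cand)
            if hit is not None:
                match = (cand, hit)
                break
        if match is None:
            tokens.append(Token(text[i], text[i], "unknown", (i, i + 1)))
            i += 1
        else:
            surface, (canonical, stype) = match
            tokens.append(Token(surface, canonical, stype, (i, i + len(surface))))
            i += len(surface)
    return tokens


def normalize_term(raw: str, dictionary: TermDictionary) -> tuple[str, bool]:
    """Map a raw term to its canonical form; idempotent by construction."""
    return dictionary.canonical(raw)


def normalize_dose(value: float, unit: str, unit_table: dict[str, float]) -> Dose:
    """Convert a (value, unit) dose to grams via the unit table.

    An unknown unit yields an unresolved Dose (grams=None) rather than an
    error, so ingestion never aborts on an unconvertible historical unit.
    """
    if value < 0:
        raise ValueError(f"dose value must be non-negative, got {value}")
    factor = unit_table.get(unit)
    grams = None if factor is None else value * factor
    return Dose(raw_value=value, raw_unit=unit, grams=grams)


# ---------------------------------------------------------------------------
# Block parsing

_FIELD_RE = re.compile(r"^【(?P<key>[^】]+)】(?P<value>.*)$")

_ESCAPES = [("\\", "\\\\"), ("\n", "\\n")]


def escape_line(s: str) -> str:
    for plain, esc in _ESCAPES:
        s = s.replace(plain, esc)
    return s


def unescape_line(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append("\n" if s[i + 1] == "n" else s[i + 1])
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def format_number(x: float) -> str:
    """Shortest decimal text that parses back to exactly ``x``."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


def _parse_composition_entry(
    entry: str, dictionary: TermDictionary, unit_table: dict[str, float]
) -> PieceUse:
    entry = entry.strip()
    note = None
    m = re.search(r"（([^）]*)）\s*$", entry)
    if m:
        note = m.group(1)
        entry = entry[: m.start()].strip()
    parts = entry.split()
    dose = None
    name = entry
    if len(parts) >= 3:
        try:
            value = float(parts[-2])
        except ValueError:
            value = None
        if value is not None:
            dose = normalize_dose(value, parts[-1], unit_table)
            name = " ".join(parts[:-2])
    if not name:
        raise ExtractionError(f"composition entry has no piece name: {entry!r}")
    canonical, _ = normalize_term(name, dictionary)
    return PieceUse(raw_name=name, canonical_name=canonical, dose=dose, processing_note=note)


def parse_blocks(text: str) -> list[str]:
    """Split a multi-record document into blocks on blank lines."""
    return [b for b in re.split(r"\n\s*\n", text.strip()) if b.strip()]


def extract_formula(
    block: str,
    dictionary: TermDictionary,
    unit_table: dict[str, float],
    formula_id: int = 0,
) -> FormulaRecord:
    """Parse one semi-structured text block into a validated record.

    Piece names are canonicalized through the dictionary (unmatched names are
    kept as-is), doses normalized to grams, and the original text preserved:
    the block's ``【原文】`` line when present, otherwise the whole block.
    """
    fields: dict[str, str] = {}
    for line in block.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _FIELD_RE.match(line)
        if m:
            fields[m.group("key")] = m.group("value")
    if "组成" not in fields or not fields["组成"].strip():
        raise ExtractionError("no recognizable composition segment (【组成】) in block")

    composition = [
        _parse_composition_entry(e, dictionary, unit_table)
        for e in fields["组成"].split("；")
        if e.strip()
    ]

    year: Optional[int] = None
    raw_year = fields.get("年份", "").strip()
    if raw_year and raw_year != "未知":
        try:
            year = int(raw_year)
        except ValueError as exc:
            raise ExtractionError(f"bad year {raw_year!r}") from exc

    def tags(key: str) -> list[str]:
        raw = fields.get(key, "").strip()
        return [t for t in raw.split("；") if t] if raw else []

    fid = formula_id
    if "编号" in fields:
        try:
            fid = int(fields["编号"])
        except ValueError as exc:
            raise ExtractionError(f"bad formula id {fields['编号']!r}") from exc

    original = unescape_line(fields["原文"]) if "原文" in fields else block

    return FormulaRecord(
        formula_id=fid,
        name=fields.get("方名", "").strip() or "未命名",
        source_book=fields.get("出处", "").strip(),
        formation_year=year,
        dynasty=fields.get("朝代", "").strip(),
        department=fields.get("科别", "").strip(),
        efficacy_tags=tags("功效"),
        nature_flavor_meridian=tags("性味归经"),
        composition=composition,
        original_text=original,
    )


def extract_corpus(
    text: str, dictionary: TermDictionary, unit_table: dict[str, float]
) -> list[FormulaRecord]:
    """Parse every block in a document; ids default to the block ordinal."""
    records = []
    for i, block in enumerate(parse_blocks(text), start=1):
        records.append(extract_formula(block, dictionary, unit_table, formula_id=i))
    return records
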