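"""Corpus-level statistics: top pieces and efficacies, era histograms,
per-piece dose-frequency tables and time distributions.

Era tables map formation years to named historical periods through ordered,
non-overlapping half-open intervals [lo, hi).  A default Chinese-dynasty
table ships with the package (``default_era_table``) but any table can be
supplied as TSV (columns era, lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .errors import DictionaryError
from .index import CorpusIndex

UNKNOWN_ERA = "unknown"


@dataclass
class EraTable:
    """Ordered (name, lo, hi) era intervals, half-open, non-overlapping."""

    eras: list[tuple[str, int, int]]

    def __post_init__(self):
        prev_hi = None
        for name, lo, hi in self.eras:
            if hi <= lo:
                raise ValueError(f"era {name!r}: empty interval [{lo}, {hi})")
            if prev_hi is not None and lo < prev_hi:
                raise ValueError(f"era {name!r} overlaps the previous era")
            prev_hi = hi

    def era_of(self, year: Optional[int]) -> str:
        if year is None:
            return UNKNOWN_ERA
        for name, lo, hi in self.eras:
            if lo <= year < hi:
                return name
        return UNKNOWN_ERA


def default_era_table() -> EraTable:
    return EraTable(
        [
            ("先秦", -2000, -221),
            ("秦汉", -221, 220),
            ("魏晋南北朝", 220, 581),
            ("隋唐五代", 581, 960),
            ("宋", 960, 1279),
            ("元", 1279, 1368),
            ("明", 1368, 1644),
            ("清", 1644, 1912),
            ("近现代", 1912, 2100),
        ]
    )


def load_era_table(path: str | Path) -> EraTable:
    """Load an era table from TSV with columns era, lo, hi."""
    eras = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["era", "lo", "hi"]:
            raise DictionaryError(f"expected header era/lo/hi, got {header!r}")
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DictionaryError(f"row {row_no}: expected 3 columns")
            eras.append((parts[0], int(parts[1]), int(parts[2])))
    return EraTable(eras)


def top_pieces(index: CorpusIndex, k: int) -> list[tuple[str, int]]:
    """The k pieces used in the most formulas; ties break lexicographically."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    ranked = sorted(
        ((p, len(ids)) for p, ids in index.piece_postings.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]


def top_efficacy(index: CorpusIndex, k: int) -> list[tuple[str, int]]:
    """The k most frequent efficacy tags; ties break lexicographically."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    ranked = sorted(
        ((t, len(ids)) for t, ids in index.efficacy_index.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]


def _histogram(years: Sequence[Optional[int]], eras: EraTable) -> list[tuple[str, int]]:
    counts = {name: 0 for name, _, _ in eras.eras}
    counts[UNKNOWN_ERA] = 0
    for y in years:
        counts[eras.era_of(y)] = counts.get(eras.era_of(y), 0) + 1
    out = [(name, counts[name]) for name, _, _ in eras.eras]
    out.append((UNKNOWN_ERA, counts[UNKNOWN_ERA]))
    return out


def dynasty_histogram(index: CorpusIndex, eras: EraTable) -> list[tuple[str, int]]:
    """Formula counts per era; years outside every era land in "unknown"."""
    return _histogram(list(index.year_of.values()), eras)


def dose_frequency(index: CorpusIndex, piece: str) -> list[tuple[float, int]]:
    """(grams, use count) pairs for a piece, grams ascending; unresolved doses
    are never counted.  Unknown pieces yield an empty list."""
    canonical, _ = index.dictionary.canonical(piece)
    obs = index.dose_observations.get(canonical)
    return list(obs.observations) if obs else []


def time_distribution(index: CorpusIndex, piece: str, eras: EraTable) -> list[tuple[str, int]]:
    """Era histogram restricted to formulas containing the piece."""
    canonical, _ = index.dictionary.canonical(piece)
    fids = index.piece_postings.get(canonical, [])
    return _histogram([index.year_of[fid] for fid in fids], eras)
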