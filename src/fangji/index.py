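"""Corpus indexing and the retrieval modes built on it.

The index holds inverted postings (piece -> formula ids, text token ->
formula ids with term frequencies), facet indexes (department, efficacy,
nature/flavor/meridian, year), and per-piece dose observations.  On top of it
sit four retrieval modes:

* piece retrieval — formulas containing ALL query pieces, ranked by the mean
  predicted importance of the query pieces in each formula (or by year);
* facet retrieval — precise conjunctive filtering on metadata;
* full-text retrieval — conjunctive token search over names and original
  text, ranked by IDF x term frequency;
* combined retrieval — the intersection of the above, ranked like piece
  retrieval when pieces are present, else like full-text.

Plus co-occurrence statistics over piece combinations.

Ranking features are always computed from the live index at query time; when
a query piece's dose is unresolved in some formula, its relative-dose feature
falls back to 0 for ranking (strict feature computation raises instead).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .corpus import (
    FormulaRecord,
    TermDictionary,
    record_from_obj,
    record_to_obj,
)
from .errors import FeatureError, QueryError
from .standardize import segment_text
from .weighting import (
    DoseObservations,
    FeatureVector,
    KernelConfig,
    WeightModel,
    compute_features,
    idf_weight,
    name_match,
    piece_frequency_fraction,
)


@dataclass
class FacetConstraints:
    """Conjunctive metadata constraints for precise retrieval."""

    department: Optional[str] = None
    efficacy_tag: Optional[str] = None
    nfm_tag: Optional[str] = None
    year_range: Optional[tuple[int, int]] = None  # inclusive [lo, hi]

    def empty(self) -> bool:
        return (
            self.department is None
            and self.efficacy_tag is None
            and self.nfm_tag is None
            and self.year_range is None
        )


@dataclass
class Query:
    """A combined query: pieces (AND), keywords (AND), facet constraints."""

    pieces: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    facets: Optional[FacetConstraints] = None
    sort: str = "importance"  # or "year"


@dataclass
class RankedResult:
    formula_id: int
    score: float
    piece_weights: dict[str, float]
    formation_year: Optional[int]
    name: str


class CorpusIndex:
    """Inverted postings, facet indexes, and dose observations for a corpus."""

    def __init__(self, records: Sequence[FormulaRecord], dictionary: TermDictionary):
        if not records:
            raise ValueError("cannot index an empty corpus")
        self.dictionary = dictionary
        self.records: dict[int, FormulaRecord] = {r.formula_id: r for r in records}
        self.n_formulas: int = len(self.records)

        piece_post: dict[str, set[int]] = {}
        token_post: dict[str, dict[int, int]] = {}
        dose_obs: dict[str, list[float]] = {}
        self.department_index: dict[str, list[int]] = {}
        self.efficacy_index: dict[str, list[int]] = {}
        self.nfm_index: dict[str, list[int]] = {}
        self.year_of: dict[int, Optional[int]] = {}

        dep_sets: dict[str, set[int]] = {}
        eff_sets: dict[str, set[int]] = {}
        nfm_sets: dict[str, set[int]] = {}

        for rec in records:
            fid = rec.formula_id
            self.year_of[fid] = rec.formation_year
            for use in rec.composition:
                piece_post.setdefault(use.canonical_name, set()).add(fid)
                if use.dose is not None and use.dose.resolved and use.dose.grams > 0:
                    dose_obs.setdefault(use.canonical_name, []).append(use.dose.grams)
            for tok in segment_text(rec.name + rec.original_text, dictionary):
                if tok.surface.isspace():
                    continue
                token_post.setdefault(tok.canonical, {}).setdefault(fid, 0)
                token_post[tok.canonical][fid] += 1
            if rec.department:
                dep_sets.setdefault(rec.department, set()).add(fid)
            for tag in rec.efficacy_tags:
                eff_sets.setdefault(tag, set()).add(fid)
            for tag in rec.nature_flavor_meridian:
                nfm_sets.setdefault(tag, set()).add(fid)

        self.piece_postings: dict[str, list[int]] = {
            p: sorted(ids) for p, ids in sorted(piece_post.items())
        }
        self.token_postings: dict[str, list[int]] = {
            t: sorted(tf) for t, tf in sorted(token_post.items())
        }
        self.token_tf: dict[str, dict[int, int]] = {
            t: dict(sorted(tf.items())) for t, tf in sorted(token_post.items())
        }
        self.dose_observations: dict[str, DoseObservations] = {
            p: DoseObservations.from_doses(p, grams)
            for p, grams in sorted(dose_obs.items())
        }
        self.department_index = {d: sorted(s) for d, s in sorted(dep_sets.items())}
        self.efficacy_index = {t: sorted(s) for t, s in sorted(eff_sets.items())}
        self.nfm_index = {t: sorted(s) for t, s in sorted(nfm_sets.items())}

    # -- persistence (JSON embedding the corpus + dictionary; rebuild on load)

    def save(self, path: str | Path) -> None:
        obj = {
            "records": [record_to_obj(r) for r in self.records.values()],
            "dictionary": [
                [raw, canon, stype]
                for raw, (canon, stype) in self.dictionary.entries.items()
            ],
        }
        Path(path).write_text(
            json.dumps(obj, ensure_ascii=False, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CorpusIndex":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        records = [record_from_obj(o) for o in obj["records"]]
        d = TermDictionary()
        for raw, canon, stype in obj["dictionary"]:
            d.add(raw, canon, stype)
        return cls(records, d)


def build_index(corpus: Sequence[FormulaRecord], dictionary: TermDictionary) -> CorpusIndex:
    """Build the full corpus index; deterministic for a given corpus."""
    return CorpusIndex(corpus, dictionary)


# ---------------------------------------------------------------------------
# Ranking helpers


def _ranking_features(
    index: CorpusIndex,
    formula: FormulaRecord,
    piece: str,
    x3_mode: str,
    kernel: KernelConfig,
) -> FeatureVector:
    """Features for ranking; unresolved doses degrade to x3=0 instead of failing."""
    try:
        return compute_features(index, formula, piece, x3_mode=x3_mode, kernel=kernel)
    except FeatureError:
        x1 = piece_frequency_fraction(index, piece)
        x2 = name_match(formula.name, piece, index.dictionary)
        return FeatureVector(x1=x1, x2=x2, x3=0.0)


def _year_key(year: Optional[int]) -> float:
    return year if year is not None else math.inf


def _rank(results: list[RankedResult], sort: str) -> list[RankedResult]:
    if sort == "importance":
        return sorted(
            results,
            key=lambda r: (-r.score, _year_key(r.formation_year), r.formula_id),
        )
    if sort == "year":
        return sorted(results, key=lambda r: (_year_key(r.formation_year), r.formula_id))
    raise QueryError(f"unknown sort mode {sort!r}")


def _score_pieces(
    index: CorpusIndex,
    model: WeightModel,
    pieces: list[str],
    fids: Sequence[int],
    sort: str,
    x3_mode: str,
    kernel: KernelConfig,
) -> list[RankedResult]:
    results = []
    for fid in fids:
        rec = index.records[fid]
        weights = {
            p: model.predict(_ranking_features(index, rec, p, x3_mode, kernel))
            for p in pieces
        }
        score = sum(weights.values()) / len(weights)
        results.append(
            RankedResult(
                formula_id=fid,
                score=score,
                piece_weights=weights,
                formation_year=rec.formation_year,
                name=rec.name,
            )
        )
    return _rank(results, sort)


# ---------------------------------------------------------------------------
# Retrieval modes


def _piece_result_set(index: CorpusIndex, pieces: list[str]) -> Optional[set[int]]:
    """Intersection of piece postings; None signals an unknown piece."""
    out: Optional[set[int]] = None
    for p in pieces:
        postings = index.piece_postings.get(p)
        if postings is None:
            warnings.warn(f"piece {p!r} is not in the corpus; empty result")
            return None
        out = set(postings) if out is None else out & set(postings)
    return out if out is not None else set()

def _canonical_pieces(index: CorpusIndex, pieces: Sequence[str]) -> list[str]:
    return [index.dictionary.canonical(p)[0] for p in pieces]


def search_pieces(
    index: CorpusIndex,
    model: WeightModel,
    pieces: Sequence[str],
    sort: str = "importance",
    x3_mode: str = "ratio",
    kernel: KernelConfig = KernelConfig(),
) -> list[RankedResult]:
    """Formulas containing ALL query pieces, ranked by mean predicted importance.

    Importance sort is score descending with ties broken by formation year
    ascending then formula id; year sort is year ascending, ties by id.
    """
    if not pieces:
        raise QueryError("piece query must name at least one piece")
    pieces = _canonical_pieces(index, pieces)
    fid_set = _piece_result_set(index, pieces)
    if not fid_set:
        return []
    return _score_pieces(index, model, pieces, sorted(fid_set), sort, x3_mode, kernel)


def search_facets(index: CorpusIndex, constraints: FacetConstraints) -> list[int]:
    """Conjunction of facet constraints; ascending formula-id list."""
    if constraints.empty():
        raise QueryError("at least one facet constraint is required")
    result: Optional[set[int]] = None

    def narrow(ids: set[int]) -> None:
        nonlocal result
        result = ids if result is None else result & ids

    if constraints.department is not None:
        narrow(set(index.department_index.get(constraints.department, [])))
    if constraints.efficacy_tag is not None:
        narrow(set(index.efficacy_index.get(constraints.efficacy_tag, [])))
    if constraints.nfm_tag is not None:
        narrow(set(index.nfm_index.get(constraints.nfm_tag, [])))
    if constraints.year_range is not None:
        lo, hi = constraints.year_range
        if hi < lo:
            raise QueryError(f"contradictory year range [{lo}, {hi}]")
        narrow(
            {
                fid
                for fid, y in index.year_of.items()
                if y is not None and lo <= y <= hi
            }
        )
    return sorted(result)


def _fulltext_candidates(index: CorpusIndex, keywords: Sequence[str]) -> tuple[set[int], list[str]]:
    tokens: list[str] = []
    for kw in keywords:
        tokens.extend(
            t.canonical for t in segment_text(kw, index.dictionary) if not t.surface.isspace()
        )
    if not tokens:
        return set(), []
    result: Optional[set[int]] = None
    for tok in tokens:
        ids = set(index.token_postings.get(tok, []))
        result = ids if result is None else result & ids
        if not result:
            return set(), tokens
    return result, tokens


def fulltext_score(index: CorpusIndex, fid: int, tokens: Sequence[str]) -> float:
    """Sum over tokens of IDF(N, document frequency) x term frequency."""
    score = 0.0
    for tok in tokens:
        tf_map = index.token_tf.get(tok, {})
        if tf_map:
            score += idf_weight(index.n_formulas, len(tf_map)) * tf_map.get(fid, 0)
    return score


def search_fulltext(index: CorpusIndex, keywords: Sequence[str]) -> list[int]:
    """Formulas whose text contains every keyword token, ranked by IDF x TF."""
    if not keywords:
        raise QueryError("keyword query must contain at least one keyword")
    candidates, tokens = _fulltext_candidates(index, keywords)
    scored = [(fulltext_score(index, fid, tokens), fid) for fid in candidates]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [fid for _, fid in scored]


def search_combined(
    index: CorpusIndex,
    model: WeightModel,
    query: Query,
    x3_mode: str = "ratio",
    kernel: KernelConfig = KernelConfig(),
) -> list[RankedResult]:
    """Intersection of piece, keyword, and facet result sets.

    Ranked like piece retrieval when pieces are present, like full-text when
    only keywords are, and by ascending formula id for facet-only queries.
    """
    has_facets = query.facets is not None and not query.facets.empty()
    if not query.pieces and not query.keywords and not has_facets:
        raise QueryError("empty query")

    result: Optional[set[int]] = None

    def narrow(ids: set[int]) -> None:
        nonlocal result
        result = ids if result is None else result & ids

    pieces = _canonical_pieces(index, query.pieces) if query.pieces else []
    tokens: list[str] = []
    if pieces:
        s = _piece_result_set(index, pieces)
        narrow(s if s is not None else set())
    if query.keywords:
        s, tokens = _fulltext_candidates(index, query.keywords)
        narrow(s)
    if has_facets:
        narrow(set(search_facets(index, query.facets)))

    fids = sorted(result) if result else []
    if pieces:
        return _score_pieces(index, model, pieces, fids, query.sort, x3_mode, kernel)
    if query.keywords:
        scored = sorted(
            ((fulltext_score(index, fid, tokens), fid) for fid in fids),
            key=lambda t: (-t[0], t[1]),
        )
        return [
            RankedResult(
                formula_id=fid,
                score=score,
                piece_weights={},
                formation_year=index.records[fid].formation_year,
                name=index.records[fid].name,
            )
            for score, fid in scored
        ]
    return [
        RankedResult(
            formula_id=fid,
            score=0.0,
            piece_weights={},
            formation_year=index.records[fid].formation_year,
            name=index.records[fid].name,
        )
        for fid in fids
    ]


# ---------------------------------------------------------------------------
# Co-occurrence statistics


def cooccurrence_count(index: CorpusIndex, pieces: Sequence[str]) -> int:
    """Number of formulas containing every listed piece."""
    if not pieces:
        raise QueryError("co-occurrence query must name at least one piece")
    result: Optional[set[int]] = None
    for p in _canonical_pieces(index, pieces):
        ids = set(index.piece_postings.get(p, []))
        result = ids if result is None else result & ids
        if not result:
            return 0
    return len(result)


def top_co_members(
    index: CorpusIndex, pieces: Sequence[str], k: int
) -> list[tuple[str, int]]:
    """The k pieces most frequently co-occurring with the whole query set.

    Counts descend; ties break lexicographically.  Query pieces themselves are
    excluded.  Fewer than k entries are returned when the vocabulary runs out.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not pieces:
        raise QueryError("co-occurrence query must name at least one piece")
    query = set(_canonical_pieces(index, pieces))
    result: Optional[set[int]] = None
    for p in query:
        ids = set(index.piece_postings.get(p, []))
        result = ids if result is None else result & ids
    tally: dict[str, int] = {}
    for fid in result or ():
        for name in {u.canonical_name for u in index.records[fid].composition}:
            if name not in query:
                tally[name] = tally.get(name, 0) + 1
    ranked = sorted(tally.items(), key=lambda t: (-t[1], t[0]))
    return ranked[:k]
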