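import itertools

import numpy as np
import pytest

import fangji as fj
import _oracles as bf
from fangji.errors import QueryError
from fangji.index import FacetConstraints, Query


class TestBuildIndex:
    def test_single_formula_corpus_posts_every_piece(self, dictionary):
        records, _ = fj.generate_corpus(fj.GeneratorConfig(seed=1, n_formulas=1))
        idx = fj.build_index(records, dictionary)
        for use in records[0].composition:
            assert idx.piece_postings[use.canonical_name] == [1]

    def test_posting_lengths_match_brute_force(self, index, corpus):
        for piece, postings in index.piece_postings.items():
            assert len(postings) == bf.frequency_count(corpus, piece)
            assert postings == sorted(postings)
            assert all(fid in index.records for fid in postings)

    def test_rebuild_is_deterministic(self, corpus, dictionary):
        a = fj.build_index(corpus, dictionary)
        b = fj.build_index(corpus, dictionary)
        assert a.piece_postings == b.piece_postings
        assert a.token_tf == b.token_tf
        assert a.department_index == b.department_index

    def test_empty_corpus_is_rejected(self, dictionary):
        with pytest.raises(ValueError):
            fj.build_index([], dictionary)

    def test_save_load_round_trip(self, index, corpus, dictionary, model, tmp_path):
        p = tmp_path / "index.json"
        index.save(p)
        loaded = fj.CorpusIndex.load(p)
        assert loaded.piece_postings == index.piece_postings
        assert loaded.token_tf == index.token_tf
        pieces = list(index.piece_postings)[:2]
        assert [r.formula_id for r in fj.search_pieces(loaded, model, pieces)] == [
            r.formula_id for r in fj.search_pieces(index, model, pieces)
        ]


class TestPieceSearch:
    def test_single_formula_match_ranks_first(self, index, corpus, model):
        # pick a piece used in exactly one formula
        piece = next(p for p, ids in index.piece_postings.items() if len(ids) == 1)
        results = fj.search_pieces(index, model, [piece])
        assert [r.formula_id for r in results] == index.piece_postings[piece]

    def test_name_and_dose_signal_dominates_constructed_corpus(self, model):
        """Of three otherwise comparable formulas, the one that both names the
        query piece in its title and uses an above-general dose ranks first."""
        d = fj.TermDictionary()
        for t in ["人参", "黄芪", "甘草"]:
            d.add(t, t, "traditional Chinese drug")

        def formula(fid, name, grams):
            comp = [
                fj.PieceUse(
                    raw_name="人参",
                    canonical_name="人参",
                    dose=fj.Dose(raw_value=grams, raw_unit="g", grams=grams),
                ),
                fj.PieceUse(
                    raw_name="甘草",
                    canonical_name="甘草",
                    dose=fj.Dose(raw_value=3, raw_unit="g", grams=3),
                ),
            ]
            return fj.FormulaRecord(
                formula_id=fid, name=name, composition=comp, formation_year=1000 + fid
            )

        recs = [
            formula(1, "安神汤", 3.0),
            formula(2, "人参汤", 9.0),  # named + high dose
            formula(3, "平胃散", 6.0),
        ]
        idx = fj.build_index(recs, d)
        results = fj.search_pieces(idx, model, ["人参"])
        assert results[0].formula_id == 2
        # hand-check the winning score: x1=1 (all 3 use it), x2=1, x3=9/6
        expected = 3.0705 + 52.8231 * 1.0 + 0.8773 * 1 + 0.0470 * (9.0 / 6.0)
        assert results[0].score == pytest.approx(expected)

    def test_unknown_piece_warns_and_returns_empty(self, index, model):
        with pytest.warns(UserWarning):
            assert fj.search_pieces(index, model, ["不存在的药"]) == []

    def test_empty_piece_list_is_an_error(self, index, model):
        with pytest.raises(QueryError):
            fj.search_pieces(index, model, [])

    def test_matches_brute_force_on_sampled_queries(
        self, index, corpus, dictionary, model
    ):
        pieces = list(index.piece_postings)
        rng = np.random.default_rng(0)
        queries = [[p] for p in pieces[:15]] + [
            [pieces[i], pieces[j]]
            for i, j in rng.integers(0, len(pieces), size=(30, 2))
            if i != j
        ]
        for q in queries:
            got = fj.search_pieces(index, model, q)
            assert {r.formula_id for r in got} == bf.piece_query_set(corpus, q)
            expected = bf.ranked_piece_query(corpus, dictionary, model, q)
            assert [r.formula_id for r in got] == [fid for fid, _, _ in expected]
            for r, (_, score, _) in zip(got, expected):
                assert r.score == pytest.approx(score, rel=1e-9)

    def test_year_sort_orders_by_formation_year(self, index, model):
        piece = max(index.piece_postings, key=lambda p: len(index.piece_postings[p]))
        results = fj.search_pieces(index, model, [piece], sort="year")
        years = [r.formation_year for r in results if r.formation_year is not None]
        assert years == sorted(years)
        # unknown years sort last
        tail_unknown = [r.formation_year for r in results][len(years) :]
        assert all(y is None for y in tail_unknown)

    def test_ranking_is_deterministic(self, corpus, dictionary, model):
        idx2 = fj.build_index(corpus, dictionary)
        piece = list(idx2.piece_postings)[0]
        a = fj.search_pieces(idx2, model, [piece])
        b = fj.search_pieces(idx2, model, [piece])
        assert [(r.formula_id, r.score) for r in a] == [
            (r.formula_id, r.score) for r in b
        ]

    def test_appending_unrelated_formula_keeps_frozen_index_ranking(
        self, corpus, dictionary, model
    ):
        """Staleness contract: with a frozen index, a new formula containing
        none of the query pieces does not perturb existing rankings."""
        idx = fj.build_index(corpus, dictionary)
        piece = list(idx.piece_postings)[1]
        before = [r.formula_id for r in fj.search_pieces(idx, model, [piece])]
        extra = fj.FormulaRecord(
            formula_id=10_000,
            name="新方",
            composition=[fj.PieceUse(raw_name="新药", canonical_name="新药")],
        )
        frozen = fj.build_index(corpus, dictionary)  # index does NOT see `extra`
        assert extra.formula_id not in frozen.records
        after = [r.formula_id for r in fj.search_pieces(frozen, model, [piece])]
        assert after == before


class TestFacetSearch:
    def test_year_range_covering_corpus_returns_known_year_ids(self, index, corpus):
        got = fj.search_facets(index, FacetConstraints(year_range=(-3000, 3000)))
        assert got == sorted(
            r.formula_id for r in corpus if r.formation_year is not None
        )

    def test_department_matches_brute_force(self, index, corpus):
        for dep in index.department_index:
            got = fj.search_facets(index, FacetConstraints(department=dep))
            assert set(got) == bf.facet_set(corpus, department=dep)
            assert got == sorted(got)

    def test_conjunction_of_constraints(self, index, corpus):
        dep = next(iter(index.department_index))
        tag = next(iter(index.efficacy_index))
        got = fj.search_facets(
            index,
            FacetConstraints(department=dep, efficacy_tag=tag, year_range=(0, 1900)),
        )
        assert set(got) == bf.facet_set(
            corpus, department=dep, efficacy_tag=tag, year_range=(0, 1900)
        )

    def test_contradictory_year_range_is_an_error(self, index):
        with pytest.raises(QueryError):
            fj.search_facets(index, FacetConstraints(year_range=(1500, 1000)))

    def test_empty_constraints_are_an_error(self, index):
        with pytest.raises(QueryError):
            fj.search_facets(index, FacetConstraints())


class TestFulltextSearch:
    def test_unique_keyword_finds_its_formula(self, corpus, dictionary, model):
        # a formula name token that appears in exactly one formula
        hits, _ = bf.fulltext(corpus, dictionary, [corpus[0].name])
        idx = fj.build_index(corpus, dictionary)
        got = fj.search_fulltext(idx, [corpus[0].name])
        assert set(got) == hits

    def test_absent_keyword_yields_empty(self, index):
        assert fj.search_fulltext(index, ["罕见奇字"]) == []

    def test_conjunction_and_scores_match_brute_force(self, index, corpus, dictionary):
        pieces = list(index.piece_postings)[:8]
        for kw in [[pieces[0]], [pieces[1], pieces[2]], [pieces[0], "汤"]]:
            got = fj.search_fulltext(index, kw)
            hits, scores = bf.fulltext(corpus, dictionary, kw)
            assert set(got) == hits
            expected = sorted(hits, key=lambda fid: (-scores[fid], fid))
            assert got == expected


class TestCombinedSearch:
    def test_pieces_only_degenerates_to_piece_search(self, index, model):
        piece = list(index.piece_postings)[0]
        combined = fj.search_combined(index, model, Query(pieces=[piece]))
        plain = fj.search_pieces(index, model, [piece])
        assert [(r.formula_id, r.score) for r in combined] == [
            (r.formula_id, r.score) for r in plain
        ]

    def test_facets_only_degenerates_to_facet_search(self, index, model):
        dep = next(iter(index.department_index))
        combined = fj.search_combined(
            index, model, Query(facets=FacetConstraints(department=dep))
        )
        assert [r.formula_id for r in combined] == fj.search_facets(
            index, FacetConstraints(department=dep)
        )

    def test_mixed_query_matches_brute_force_intersection(
        self, index, corpus, dictionary, model
    ):
        rng = np.random.default_rng(17)
        pieces = list(index.piece_postings)
        deps = list(index.department_index)
        for _ in range(20):
            q = Query(
                pieces=[pieces[int(rng.integers(len(pieces)))]],
                keywords=[pieces[int(rng.integers(len(pieces)))]],
                facets=FacetConstraints(department=deps[int(rng.integers(len(deps)))]),
            )
            got = {r.formula_id for r in fj.search_combined(index, model, q)}
            expected = (
                bf.piece_query_set(corpus, q.pieces)
                & bf.fulltext(corpus, dictionary, q.keywords)[0]
                & bf.facet_set(corpus, department=q.facets.department)
            )
            assert got == expected

    def test_empty_query_is_an_error(self, index, model):
        with pytest.raises(QueryError):
            fj.search_combined(index, model, Query())


class TestCooccurrence:
    def test_single_piece_count_is_posting_length(self, index):
        for piece in list(index.piece_postings)[:10]:
            assert fj.cooccurrence_count(index, [piece]) == len(
                index.piece_postings[piece]
            )

    def test_pair_counts_match_brute_force_and_respect_bound(self, index, corpus):
        pieces = list(index.piece_postings)[:12]
        for a, b in itertools.combinations(pieces, 2):
            got = fj.cooccurrence_count(index, [a, b])
            assert got == bf.cooccurrence(corpus, [a, b])
            assert got <= min(
                fj.cooccurrence_count(index, [a]), fj.cooccurrence_count(index, [b])
            )

    def test_forced_companion_ranks_first(self, dictionary, model):
        d = fj.TermDictionary()
        for t in ["人参", "白术", "茯苓", "陈皮"]:
            d.add(t, t, "traditional Chinese drug")

        def rec(fid, names):
            return fj.FormulaRecord(
                formula_id=fid,
                name=f"方{fid}",
                composition=[
                    fj.PieceUse(raw_name=n, canonical_name=n) for n in names
                ],
            )

        recs = [
            rec(1, ["人参", "白术", "茯苓"]),
            rec(2, ["人参", "白术", "茯苓", "陈皮"]),
            rec(3, ["人参", "白术", "茯苓"]),
        ]
        idx = fj.build_index(recs, d)
        top = fj.top_co_members(idx, ["人参", "白术"], k=5)
        assert top[0] == ("茯苓", fj.cooccurrence_count(idx, ["人参", "白术"]))

    def test_top_co_members_match_brute_force(self, index, corpus):
        pieces = list(index.piece_postings)[:2]
        got = fj.top_co_members(index, pieces, k=10)
        tally = bf.co_member_tally(corpus, pieces)
        expected = sorted(tally.items(), key=lambda t: (-t[1], t[0]))[:10]
        assert got == expected

    def test_k_larger_than_vocabulary_returns_full_tally(self, index, corpus):
        pieces = list(index.piece_postings)[:1]
        got = fj.top_co_members(index, pieces, k=10**6)
        assert len(got) == len(bf.co_member_tally(corpus, pieces))

    def test_nonpositive_k_is_an_error(self, index):
        with pytest.raises(ValueError):
            fj.top_co_members(index, ["人参"], k=0)
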