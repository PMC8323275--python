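"""Brute-force reference computations, independent of CorpusIndex.

Every function here works by direct scans over the record list, so the
indexed/ranked implementations can be checked against first principles.
"""

import math

from fangji import segment_text


def frequency_count(records, piece):
    return sum(
        1 for r in records if any(u.canonical_name == piece for u in r.composition)
    )


def all_grams(records, piece):
    out = []
    for r in records:
        for u in r.composition:
            if u.canonical_name == piece and u.dose is not None and u.dose.resolved:
                out.append(u.dose.grams)
    return out


def general_dose(records, piece):
    grams = sorted(all_grams(records, piece))
    return sum(grams) / len(grams)


def name_match(formula_name, piece, dictionary):
    syns = {raw for raw, (canon, _) in dictionary.entries.items() if canon == piece}
    syns.add(piece)
    return int(any(s and s in formula_name for s in syns))


def features(records, dictionary, record, piece):
    x1 = frequency_count(records, piece) / len(records)
    x2 = name_match(record.name, piece, dictionary)
    use = next(u for u in record.composition if u.canonical_name == piece)
    x3 = use.dose.grams / general_dose(records, piece)
    return (x1, x2, x3)


def predict(model, x):
    return model.w0 + model.w1 * x[0] + model.w2 * x[1] + model.w3 * x[2]


def piece_query_set(records, pieces):
    out = set()
    for r in records:
        names = {u.canonical_name for u in r.composition}
        if all(p in names for p in pieces):
            out.add(r.formula_id)
    return out


def ranked_piece_query(records, dictionary, model, pieces, sort="importance"):
    by_id = {r.formula_id: r for r in records}
    fids = piece_query_set(records, pieces)
    scored = []
    for fid in fids:
        rec = by_id[fid]
        score = sum(
            predict(model, features(records, dictionary, rec, p)) for p in pieces
        ) / len(pieces)
        scored.append((fid, score, rec.formation_year))
    ykey = lambda y: y if y is not None else math.inf
    if sort == "importance":
        scored.sort(key=lambda t: (-t[1], ykey(t[2]), t[0]))
    else:
        scored.sort(key=lambda t: (ykey(t[2]), t[0]))
    return scored


def facet_set(records, department=None, efficacy_tag=None, nfm_tag=None, year_range=None):
    out = set()
    for r in records:
        if department is not None and r.department != department:
            continue
        if efficacy_tag is not None and efficacy_tag not in r.efficacy_tags:
            continue
        if nfm_tag is not None and nfm_tag not in r.nature_flavor_meridian:
            continue
        if year_range is not None:
            lo, hi = year_range
            if r.formation_year is None or not (lo <= r.formation_year <= hi):
                continue
        out.add(r.formula_id)
    return out


def fulltext(records, dictionary, keywords):
    """(result set, scores) by direct per-document token counting."""
    tokens = []
    for kw in keywords:
        tokens.extend(
            t.canonical for t in segment_text(kw, dictionary) if not t.surface.isspace()
        )
    doc_tokens = {}
    for r in records:
        counts = {}
        for t in segment_text(r.name + r.original_text, dictionary):
            if not t.surface.isspace():
                counts[t.canonical] = counts.get(t.canonical, 0) + 1
        doc_tokens[r.formula_id] = counts
    if not tokens:
        return set(), {}
    hits = {
        fid for fid, counts in doc_tokens.items() if all(t in counts for t in tokens)
    }
    df = {
        t: sum(1 for counts in doc_tokens.values() if t in counts) for t in set(tokens)
    }
    scores = {}
    for fid in hits:
        scores[fid] = sum(
            math.log(len(records) / df[t]) * doc_tokens[fid].get(t, 0)
            for t in tokens
            if df[t] > 0
        )
    return hits, scores


def cooccurrence(records, pieces):
    return len(piece_query_set(records, pieces))


def co_member_tally(records, pieces):
    tally = {}
    for r in records:
        names = {u.canonical_name for u in r.composition}
        if all(p in names for p in pieces):
            for name in names - set(pieces):
                tally[name] = tally.get(name, 0) + 1
    return tally
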