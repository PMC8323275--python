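"""Deterministic synthetic formula corpora with known statistical structure.

The generator emulates the corpus features the importance model feeds on:

* piece usage follows a Zipf rank-frequency law (a few workhorse herbs, a
  long tail), sampled without replacement per formula;
* each piece has a characteristic lognormal dose law; the drawn dose is
  scaled by the piece's latent role in the formula (Monarch doses run
  higher), so dose carries a real importance signal;
* with configurable probability a formula's name embeds its Monarch piece
  (e.g. 人参汤), so the name-match feature is informative;
* metadata (years, departments, efficacy and nature/flavor/meridian tags)
  is drawn from configurable vocabularies.

One integer seed drives independent sub-streams (piece laws, compositions,
names, metadata) derived via ``numpy.random.SeedSequence.spawn``, so adding
a field to one stream never perturbs the others.

The module also provides :func:`generate_annotated_rows` (training rows from
known coefficients, for parameter-recovery studies) and
:func:`reference_rows` (the bundled nine-row excerpt of the expert-annotated
training data that accompanies the reference coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .corpus import Dose, FormulaRecord, PieceUse, TermDictionary
from .standardize import escape_line, format_number
from .stats import default_era_table
from .weighting import AnnotatedRow, FeatureVector

REAL_PIECES = ["人参", "白术", "茯苓", "陈皮", "蛇含石"]

_PIECE_CHARS = "芍药苓桂枝草仁花子实叶根皮藤香砂石母贝玄冬夏青黄白紫赤金银木火土海山川云龙凤"
_NAME_CHARS = "平安康宁和顺泰吉祥瑞惠济永昌"
_NAME_SUFFIXES = ["汤", "丸", "散", "饮", "膏"]
_PROCESSING_NOTES = ["炙", "炒", "煅", "酒洗"]


class GeneratorConfig(BaseModel):
    """Tunable knobs of the corpus generator; defaults give a small but
    statistically realistic corpus."""

    seed: int = 0
    n_formulas: int = Field(default=200, ge=1)
    vocab_size: int = Field(default=100, ge=12)
    zipf_exponent: float = Field(default=1.0, gt=0)
    dose_log_mean_range: tuple[float, float] = (0.7, 2.7)  # exp -> ~2..15 g
    dose_log_sd_range: tuple[float, float] = (0.2, 0.5)
    name_embed_prob: float = Field(default=0.7, ge=0, le=1)
    historical_unit_prob: float = Field(default=0.15, ge=0, le=1)
    processing_note_prob: float = Field(default=0.2, ge=0, le=1)
    unknown_year_prob: float = Field(default=0.1, ge=0, le=1)
    year_span: tuple[int, int] = (-200, 1912)
    departments: list[str] = Field(
        default_factory=lambda: ["内科", "外科", "妇科", "儿科", "五官科"]
    )
    efficacy_vocab: list[str] = Field(
        default_factory=lambda: ["补气", "活血", "清热", "解表", "安神", "止咳", "利水", "温里"]
    )
    nfm_vocab: list[str] = Field(
        default_factory=lambda: ["温", "寒", "平", "甘", "苦", "辛", "归脾经", "归肺经", "归心经"]
    )


@dataclass
class GroundTruth:
    """Latent structure behind a generated corpus: per-(formula, piece) role
    weights on the 4..1 scale, per-piece lognormal dose parameters, and the
    generating coefficients when rows come from the linear model."""

    roles: dict[tuple[int, str], int] = field(default_factory=dict)
    dose_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    coefficients: Optional[tuple[float, float, float, float]] = None


def piece_vocabulary(config: GeneratorConfig) -> list[str]:
    """Deterministic piece vocabulary: a small real-name subset plus synthetic
    two-character names."""
    vocab = list(REAL_PIECES)
    chars = _PIECE_CHARS
    for a in chars:
        for b in chars:
            if len(vocab) >= config.vocab_size:
                return vocab[: config.vocab_size]
            name = a + b
            if name not in vocab:
                vocab.append(name)
    raise ValueError(f"vocab_size {config.vocab_size} exceeds the name pool")


def generator_dictionary(config: GeneratorConfig) -> TermDictionary:
    """Term dictionary covering the generator's vocabulary (plus the 蛇黄
    synonym of 蛇含石, so standardization examples work out of the box)."""
    d = TermDictionary()
    for name in piece_vocabulary(config):
        d.add(name, name, "traditional Chinese drug")
    d.add("蛇黄", "蛇含石", "traditional Chinese drug")
    for tag in config.efficacy_vocab:
        d.add(tag, tag, "efficacy")
    for tag in config.nfm_vocab:
        d.add(tag, tag, "nature and flavor")
    return d


def _zipf_probs(v: int, s: float) -> np.ndarray:
    ranks = np.arange(1, v + 1, dtype=float)
    p = ranks**-s
    return p / p.sum()


def generate_corpus(config: GeneratorConfig) -> tuple[list[FormulaRecord], GroundTruth]:
    """Generate a corpus and its latent ground truth; deterministic per seed."""
    ss = np.random.SeedSequence(config.seed)
    s_params, s_comp, s_names, s_meta = [np.random.default_rng(c) for c in ss.spawn(4)]

    vocab = piece_vocabulary(config)
    probs = _zipf_probs(config.vocab_size, config.zipf_exponent)
    mu_lo, mu_hi = config.dose_log_mean_range
    sd_lo, sd_hi = config.dose_log_sd_range
    dose_params = {
        p: (float(s_params.uniform(mu_lo, mu_hi)), float(s_params.uniform(sd_lo, sd_hi)))
        for p in vocab
    }

    truth = GroundTruth(dose_params=dose_params)
    eras = default_era_table()
    records: list[FormulaRecord] = []
    for fid in range(1, config.n_formulas + 1):
        k = int(s_comp.integers(2, min(12, config.vocab_size) + 1))
        chosen = list(s_comp.choice(config.vocab_size, size=k, replace=False, p=probs))
        pieces = [vocab[i] for i in chosen]
        s_comp.shuffle(pieces)
        roles = [4, 3] + [int(s_comp.integers(1, 3)) for _ in range(k - 2)]

        composition: list[PieceUse] = []
        for piece, role in zip(pieces, roles):
            truth.roles[(fid, piece)] = role
            mu, sd = dose_params[piece]
            grams_draw = float(np.exp(s_comp.normal(mu, sd))) * (role / 2.0)
            if s_comp.random() < config.historical_unit_prob:
                unit, factor = "钱", 3.73
            else:
                unit, factor = "g", 1.0
            raw_value = max(0.1, round(grams_draw / factor, 1))
            note = (
                str(s_comp.choice(_PROCESSING_NOTES))
                if s_comp.random() < config.processing_note_prob
                else None
            )
            composition.append(
                PieceUse(
                    raw_name=piece,
                    canonical_name=piece,
                    dose=Dose(raw_value=raw_value, raw_unit=unit, grams=raw_value * factor),
                    processing_note=note,
                )
            )

        suffix = _NAME_SUFFIXES[int(s_names.integers(0, len(_NAME_SUFFIXES)))]
        if s_names.random() < config.name_embed_prob:
            name = pieces[0] + suffix  # pieces[0] holds role 4 (Monarch)
        else:
            a = _NAME_CHARS[int(s_names.integers(0, len(_NAME_CHARS)))]
            b = _NAME_CHARS[int(s_names.integers(0, len(_NAME_CHARS)))]
            name = a + b + suffix

        if s_meta.random() < config.unknown_year_prob:
            year = None
        else:
            year = int(s_meta.integers(config.year_span[0], config.year_span[1] + 1))
        department = config.departments[int(s_meta.integers(0, len(config.departments)))]
        n_eff = int(s_meta.integers(1, 4))
        efficacy = [
            config.efficacy_vocab[i]
            for i in sorted(
                s_meta.choice(len(config.efficacy_vocab), size=n_eff, replace=False)
            )
        ]
        n_nfm = int(s_meta.integers(1, 4))
        nfm = [
            config.nfm_vocab[i]
            for i in sorted(s_meta.choice(len(config.nfm_vocab), size=n_nfm, replace=False))
        ]

        comp_text = "、".join(p.raw_name for p in composition)
        original = f"{name}，{'、'.join(efficacy)}。组成：{comp_text}。"

        records.append(
            FormulaRecord(
                formula_id=fid,
                name=name,
                source_book=f"合成书卷{1 + fid % 7}",
                formation_year=year,
                dynasty=eras.era_of(year) if year is not None else "",
                department=department,
                efficacy_tags=efficacy,
                nature_flavor_meridian=nfm,
                composition=composition,
                original_text=original,
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Text-block rendering (inverse of standardize.extract_formula)


def render_block(rec: FormulaRecord) -> str:
    """Render one record as a labeled text block; extract_formula inverts it."""
    lines = [f"【编号】{rec.formula_id}", f"【方名】{rec.name}"]
    if rec.dynasty:
        lines.append(f"【朝代】{rec.dynasty}")
    lines.append(f"【年份】{rec.formation_year if rec.formation_year is not None else '未知'}")
    if rec.department:
        lines.append(f"【科别】{rec.department}")
    if rec.efficacy_tags:
        lines.append(f"【功效】{'；'.join(rec.efficacy_tags)}")
    if rec.nature_flavor_meridian:
        lines.append(f"【性味归经】{'；'.join(rec.nature_flavor_meridian)}")
    entries = []
    for p in rec.composition:
        e = p.raw_name
        if p.dose is not None:
            e += f" {format_number(p.dose.raw_value)} {p.dose.raw_unit}"
        if p.processing_note is not None:
            e += f"（{p.processing_note}）"
        entries.append(e)
    lines.append(f"【组成】{'；'.join(entries)}")
    if rec.source_book:
        lines.append(f"【出处】{rec.source_book}")
    lines.append(f"【原文】{escape_line(rec.original_text)}")
    return "\n".join(lines)


def render_blocks(corpus: Sequence[FormulaRecord]) -> list[str]:
    """Render a whole corpus; one block per formula, same order."""
    return [render_block(r) for r in corpus]


# ---------------------------------------------------------------------------
# Annotated training rows


def generate_annotated_rows(
    coefficients: tuple[float, float, float, float],
    noise_sd: float,
    n: int,
    seed: int,
    integer_labels: bool = False,
) -> list[AnnotatedRow]:
    """Rows from the affine model y = w0 + w1 x1 + w2 x2 + w3 x3 + noise.

    Feature ranges follow the magnitudes of the reference annotation table:
    x1 uniform in [1e-4, 0.01], x2 Bernoulli(0.3), x3 uniform in [0.01, 3].
    With ``integer_labels`` the latent y is rounded and clipped to 1..4.
    """
    if noise_sd < 0:
        raise ValueError(f"noise sd must be non-negative, got {noise_sd}")
    if n < 4:
        raise ValueError(f"need n >= 4 rows, got {n}")
    w0, w1, w2, w3 = coefficients
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(1e-4, 0.01, size=n)
    x2 = (rng.random(size=n) < 0.3).astype(int)
    x3 = rng.uniform(0.01, 3.0, size=n)
    y = w0 + w1 * x1 + w2 * x2 + w3 * x3 + rng.normal(0.0, noise_sd, size=n)
    if integer_labels:
        y = np.clip(np.rint(y), 1, 4)
    return [
        AnnotatedRow(
            formula_id=i + 1,
            piece_id=10000 + i,
            piece=f"synthetic-piece-{i + 1}",
            annotated_weight=float(y[i]),
            features=FeatureVector(x1=float(x1[i]), x2=int(x2[i]), x3=float(x3[i])),
        )
        for i in range(n)
    ]


def reference_rows() -> list[AnnotatedRow]:
    """The bundled nine-row excerpt of the expert annotation set.

    These (formula, piece) rows carry Monarch..Guide weights and precomputed
    features on the 38,000-formula corpus the reference coefficients were
    trained on; they serve as a frozen check of the reference model.  The
    published rendering of this table is typographically run together; the
    x3 cells of the cinnabar and clove rows admit an alternative reading with
    one more trailing digit (0.02241 / 0.02661), and the Damangcao Powder
    formula id is not legible (recorded here as 3).
    """
    raw = [
        (2, 19153, "Gentiana macrophylla", 4, 0.00064414, 1, 0.0666),
        (3, 19381, "shikimic", 4, 0.00052605, 1, 0.0523),
        (14, 17578, "cinnabar", 4, 0.00228797, 0, 0.0224),
        (14, 19988, "clove", 3, 0.00022269, 0, 0.0266),
        (14, 17878, "lead powder", 3, 0.00022269, 0, 0.038),
        (15, 17591, "dendrob", 2, 0.00028504, 0, 0.098),
        (15, 19972, "ginseng", 4, 0.00248455, 0, 0.0349),
        (18, 17546, "tatarian aster", 3, 0.00487358, 0, 0.1042),
        (19, 17820, "niter", 3, 0.00156434, 0, 0.0529),
    ]
    return [
        AnnotatedRow(
            formula_id=fid,
            piece_id=pid,
            piece=piece,
            annotated_weight=w,
            features=FeatureVector(x1=x1, x2=x2, x3=x3),
        )
        for fid, pid, piece, w, x1, x2, x3 in raw
    ]
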