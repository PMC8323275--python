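"""Ingredient-importance weighting: features, dose kernel, and linear model.

The importance of a decoction piece within a formula is modeled as an affine
function of three features::

    y = w0 + w1*x1 + w2*x2 + w3*x3

* ``x1`` — how commonly the piece is used: the fraction of corpus formulas
  containing it, ``f(t)/N``.
* ``x2`` — whether the piece (or any dictionary synonym) appears in the
  formula's name, as a 0/1 string-match indicator.
* ``x3`` — the piece's dose relative to its corpus-wide "general dose"
  (count-weighted mean of observed doses in grams).  A Gaussian
  kernel-density *dose relevance* is available as an alternative x3.

``y`` is trained against expert annotations on the Monarch–Minister–
Assistant–Guide (君臣佐使) scale, encoded 4..1.  The model is ordinary least
squares; :class:`IngredientWeightRegressor` is a scikit-learn estimator so it
composes with sklearn pipelines and model selection, and the module-level
functions are thin wrappers over it.

A reference coefficient set trained on 400 expert-annotated rows ships as
:func:`reference_model` (w0=3.0705, w1=52.8231, w2=0.8773, w3=0.0470, with a
reported train deviation of 0.719 weight units).

The *dose relevance* of a query dose t is a Gaussian kernel density estimate
over the piece's n distinct observed doses t_i::

    f(t | S) = 1/(n h sqrt(2 pi)) * sum_i exp(-(t - t_i)^2 / (2 h^2))

with dose distance taken as the absolute difference of grams-normalized
doses.  The 1/h factor makes each kernel integrate to one, so f is a proper
density with unit total mass.  The bandwidth h defaults to Silverman's rule
1.06 * sigma * m^(-1/5) on the piece's observed doses (floored at 0.1 g).

Rarity of a piece across the corpus is the usual inverse document frequency
``w(t) = ln(N / f(t))``, used for full-text ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .corpus import FormulaRecord, TermDictionary
from .errors import FeatureError, FitError

if TYPE_CHECKING:  # pragma: no cover
    from .index import CorpusIndex


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class FeatureVector:
    """The (x1, x2, x3) feature triple for one (formula, piece) pair."""

    x1: float  # occurrence-frequency fraction, in [0, 1]
    x2: int  # name-match indicator, 0 or 1
    x3: float  # relative-dose feature, >= 0

    def __post_init__(self):
        if not 0.0 <= self.x1 <= 1.0:
            raise ValueError(f"x1 must lie in [0, 1], got {self.x1}")
        if self.x2 not in (0, 1):
            raise ValueError(f"x2 must be 0 or 1, got {self.x2}")
        if self.x3 < 0:
            raise ValueError(f"x3 must be non-negative, got {self.x3}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)


@dataclass
class DoseObservations:
    """Per-piece multiset of corpus doses on a grams scale.

    ``observations`` holds (grams, count) pairs, grams ascending and distinct;
    ``n_distinct`` — the number of different doses — is its length.
    """

    piece: str
    observations: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self):
        for g, c in self.observations:
            if g <= 0:
                raise ValueError(f"dose grams must be positive, got {g}")
            if c <= 0:
                raise ValueError(f"count must be positive, got {c}")
        self.observations = sorted(self.observations)

    @classmethod
    def from_doses(cls, piece: str, grams: Sequence[float]) -> "DoseObservations":
        counts: dict[float, int] = {}
        for g in grams:
            counts[g] = counts.get(g, 0) + 1
        return cls(piece=piece, observations=sorted(counts.items()))

    @property
    def n_distinct(self) -> int:
        return len(self.observations)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.observations)


@dataclass(frozen=True)
class KernelConfig:
    """Bandwidth policy for the dose-relevance kernel."""

    bandwidth_rule: str = "silverman"  # "fixed" or "silverman"
    h: Optional[float] = None  # required when fixed

    def __post_init__(self):
        if self.bandwidth_rule not in ("fixed", "silverman"):
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed" and (self.h is None or self.h <= 0):
            raise ValueError("fixed bandwidth requires h > 0")


@dataclass
class AnnotatedRow:
    """One expert-annotated (formula, piece) training row.

    ``annotated_weight`` follows the 4 = Monarch, 3 = Minister, 2 = Assistant,
    1 = Guide convention; simulation may carry the continuous latent value.
    """

    formula_id: int
    piece_id: int
    piece: str
    annotated_weight: float
    features: FeatureVector

    def __post_init__(self):
        w = self.annotated_weight
        if float(w).is_integer() and w not in (1, 2, 3, 4):
            raise ValueError(f"integer annotated weight must be in 1..4, got {w}")


# ---------------------------------------------------------------------------
# Elementary feature computations


def general_dose(obs: DoseObservations) -> float:
    """Count-weighted mean of a piece's observed doses, in grams."""
    if obs.n_distinct == 0:
        raise ValueError(f"no dose observations for piece {obs.piece!r}")
    total = obs.total_count
    return sum(g * c for g, c in obs.observations) / total


def dose_ratio(dose_grams: float, obs: DoseObservations) -> float:
    """Ratio of a dose to the piece's general dose."""
    g = general_dose(obs)
    if g == 0:
        raise ValueError("general dose is zero")
    return dose_grams / g


def silverman_bandwidth(obs: DoseObservations, floor: float = 0.1) -> float:
    """Silverman's rule 1.06*sigma*m^(-1/5) on the observed grams, floored."""
    m = obs.total_count
    mean = general_dose(obs)
    var = sum(c * (g - mean) ** 2 for g, c in obs.observations) / m
    h = 1.06 * math.sqrt(var) * m ** (-0.2)
    return max(h, floor)


def bandwidth(obs: DoseObservations, config: KernelConfig) -> float:
    if config.bandwidth_rule == "fixed":
        return float(config.h)  # validated positive at construction
    return silverman_bandwidth(obs)


def dose_relevance(
    dose_grams: float, obs: DoseObservations, config: KernelConfig = KernelConfig()
) -> float:
    """Gaussian KDE of the piece's distinct doses, evaluated at ``dose_grams``.

    Each of the n distinct doses contributes one unit-mass Gaussian kernel, so
    the result integrates to 1 over the dose axis.
    """
    if obs.n_distinct == 0:
        raise ValueError(f"no dose observations for piece {obs.piece!r}")
    h = bandwidth(obs, config)
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    n = obs.n_distinct
    s = sum(math.exp(-((dose_grams - g) ** 2) / (2 * h * h)) for g, _ in obs.observations)
    return s / (n * h * math.sqrt(2 * math.pi))


def idf_weight(n: int, f_t: int) -> float:
    """Inverse document frequency ln(n / f_t); 0 for a piece in every formula."""
    if f_t <= 0 or f_t > n:
        raise ValueError(f"require 1 <= f_t <= n, got f_t={f_t}, n={n}")
    return math.log(n / f_t)


def piece_frequency_fraction(index: "CorpusIndex", piece: str) -> float:
    """f(t)/N: fraction of corpus formulas containing the piece (0 if absent)."""
    postings = index.piece_postings.get(piece)
    if not postings:
        return 0.0
    return len(postings) / index.n_formulas


def name_match(formula_name: str, piece: str, dictionary: TermDictionary) -> int:
    """1 iff the piece's canonical name or any dictionary synonym occurs as a
    substring of the formula name (after canonicalizing the piece), else 0."""
    canonical, _ = dictionary.canonical(piece)
    names = dictionary.synonyms(canonical) or {canonical}
    names.add(canonical)
    return int(any(n and n in formula_name for n in names))


def compute_features(
    index: "CorpusIndex",
    formula: FormulaRecord,
    piece: str,
    x3_mode: str = "ratio",
    kernel: KernelConfig = KernelConfig(),
) -> FeatureVector:
    """Assemble the (x1, x2, x3) feature triple for one (formula, piece) pair.

    ``x3_mode`` selects the relative-dose feature: ``"ratio"`` (dose over
    general dose, the default) or ``"kernel"`` (Gaussian dose relevance).
    """
    use = next((p for p in formula.composition if p.canonical_name == piece), None)
    if use is None:
        raise FeatureError(f"piece {piece!r} not in formula {formula.formula_id}")
    if use.dose is None or not use.dose.resolved:
        raise FeatureError(
            f"piece {piece!r} in formula {formula.formula_id} has no resolved dose (grams)"
        )
    x1 = piece_frequency_fraction(index, piece)
    x2 = name_match(formula.name, piece, index.dictionary)
    obs = index.dose_observations.get(piece)
    if obs is None or obs.n_distinct == 0:
        raise FeatureError(f"no corpus dose observations for piece {piece!r}")
    if x3_mode == "ratio":
        x3 = dose_ratio(use.dose.grams, obs)
    elif x3_mode == "kernel":
        x3 = dose_relevance(use.dose.grams, obs, kernel)
    else:
        raise ValueError(f"unknown x3_mode {x3_mode!r}")
    return FeatureVector(x1=x1, x2=x2, x3=x3)


# ---------------------------------------------------------------------------
# The linear importance model


class IngredientWeightRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares over the three importance features.

    A scikit-learn regressor: ``fit(X, y)`` with X of shape (n_samples, 3)
    holding (x1, x2, x3) rows, ``predict(X)`` the affine combination.  Fitted
    attributes follow sklearn conventions (``coef_``, ``intercept_``); the
    training root-mean-square deviation is kept as ``train_rms_``.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < X.shape[1] + 1:
            raise FitError(
                f"need at least {X.shape[1] + 1} rows to fit, got {X.shape[0]}"
            )
        design = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FitError("design matrix is rank deficient")
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.n_features_in_ = X.shape[1]
        self.n_train_ = int(X.shape[0])
        resid = y - design @ beta
        self.train_rms_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


@dataclass
class WeightModel:
    """Coefficients of the affine importance model plus fit metadata."""

    w0: float
    w1: float
    w2: float
    w3: float
    n_train: int = 0
    train_rms: float = 0.0

    def predict(self, v: FeatureVector) -> float:
        return self.w0 + self.w1 * v.x1 + self.w2 * v.x2 + self.w3 * v.x3

    def to_dict(self) -> dict:
        return {
            "w0": self.w0,
            "w1": self.w1,
            "w2": self.w2,
            "w3": self.w3,
            "n_train": self.n_train,
            "train_rms": self.train_rms,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "WeightModel":
        return cls(**obj)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "WeightModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def reference_model() -> WeightModel:
    """The bundled reference coefficient set (trained on 400 annotated rows)."""
    return WeightModel(
        w0=3.0705, w1=52.8231, w2=0.8773, w3=0.0470, n_train=400, train_rms=0.719
    )


def fit_weight_model(rows: Sequence[AnnotatedRow]) -> WeightModel:
    """OLS fit of the importance model on annotated rows (needs >= 4 rows)."""
    if len(rows) < 4:
        raise FitError(f"need at least 4 annotated rows, got {len(rows)}")
    X = np.array([r.features.as_array() for r in rows])
    y = np.array([r.annotated_weight for r in rows], dtype=float)
    est = IngredientWeightRegressor().fit(X, y)
    return WeightModel(
        w0=est.intercept_,
        w1=float(est.coef_[0]),
        w2=float(est.coef_[1]),
        w3=float(est.coef_[2]),
        n_train=est.n_train_,
        train_rms=est.train_rms_,
    )


def predict_weight(model: WeightModel, v: FeatureVector) -> float:
    """Affine prediction of a piece's importance from its feature triple."""
    return model.predict(v)


def evaluate_model(model: WeightModel, rows: Sequence[AnnotatedRow]) -> float:
    """Root-mean-square deviation between predictions and annotated weights."""
    if not rows:
        raise ValueError("no rows to evaluate")
    errs = [model.predict(r.features) - r.annotated_weight for r in rows]
    return math.sqrt(sum(e * e for e in errs) / len(errs))


# ---------------------------------------------------------------------------
# Annotated-row CSV exchange (columns mirror the reference annotation table)

ROW_COLUMNS = ["formula_id", "piece_id", "piece", "annotated_weight", "x1", "x2", "x3"]


def rows_to_csv(rows: Sequence[AnnotatedRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "formula_id": r.formula_id,
                "piece_id": r.piece_id,
                "piece": r.piece,
                "annotated_weight": r.annotated_weight,
                "x1": r.features.x1,
                "x2": r.features.x2,
                "x3": r.features.x3,
            }
            for r in rows
        ],
        columns=ROW_COLUMNS,
    )
    df.to_csv(path, index=False)


def rows_from_csv(path: str | Path) -> list[AnnotatedRow]:
    df = pd.read_csv(path)
    missing = set(ROW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rows file missing columns: {sorted(missing)}")
    return [
        AnnotatedRow(
            formula_id=int(r.formula_id),
            piece_id=int(r.piece_id),
            piece=str(r.piece),
            annotated_weight=float(r.annotated_weight),
            features=FeatureVector(x1=float(r.x1), x2=int(r.x2), x3=float(r.x3)),
        )
        for r in df.itertuples()
    ]
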