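"""Normalization and aggregation of the individual scorers into the ensemble.

Each selected method's raw scores are scaled to the common interval
[0, 1/n] (n = number of selected methods) by dividing by the column maximum:
pure scaling preserves zeros — in particular the mandated zero of
FCBF-eliminated features — and conserves all ratios between feature
importances.  The ensemble importance of a feature is the sum of its
normalized scores, a value in [0, 1].
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import EfsWarning, FeatureTable, RunConfig
from .preprocess import PreprocessReport, check_degenerate, filter_na
from .scorers import (
    RawScoreVector,
    score_correlation,
    score_forest,
    score_logreg,
    score_median,
)

__all__ = [
    "ImportanceMatrix",
    "EnsembleResult",
    "normalize_scores",
    "aggregate_ensemble",
    "select_features",
    "run_efs",
]

logger = logging.getLogger(__name__)

FOREST_METHODS = ("rf_mdi", "rf_error", "cf_error", "cf_auc")


class EmptySelectionError(ValueError):
    """Raised when a selection rule returns no features."""


@dataclass(frozen=True)
class ImportanceMatrix:
    """Features x selected methods, each column normalized to [0, 1/n]."""

    feature_names: tuple[str, ...]
    methods: tuple[str, ...]
    normalized: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.normalized, index=list(self.feature_names), columns=list(self.methods)
        )


@dataclass(frozen=True)
class EnsembleResult:
    importance_matrix: ImportanceMatrix
    ensemble_scores: np.ndarray
    ranking: tuple[str, ...]
    selected: tuple[str, ...]
    config_used: RunConfig | None = None
    preprocess_report: PreprocessReport | None = None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.importance_matrix.feature_names

    def scores_by_name(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.ensemble_scores.tolist()))


def normalize_scores(raw: RawScoreVector | np.ndarray, n_methods: int) -> np.ndarray:
    """Scale a raw score vector to [0, 1/n_methods].

    Negative raw scores (possible for permutation importances) are clipped to
    zero first; the clipped vector is divided by its maximum and by
    ``n_methods``.  An all-non-positive vector maps to all zeros.
    """
    if n_methods < 1:
        raise ValueError("n_methods must be >= 1")
    scores = raw.scores if isinstance(raw, RawScoreVector) else np.asarray(raw, dtype=float)
    clipped = np.clip(scores, 0.0, None)
    peak = clipped.max() if clipped.size else 0.0
    if peak <= 0.0:
        return np.zeros_like(clipped)
    return clipped / peak / n_methods


def aggregate_ensemble(
    columns: Mapping[str, np.ndarray], feature_names: Sequence[str]
) -> EnsembleResult:
    """Assemble normalized columns into an importance matrix and rank features.

    ``columns`` maps method name -> normalized vector (insertion order is the
    method order).  Ensemble score = row sum; ranking is by decreasing score,
    ties broken by input column order.
    """
    names = tuple(feature_names)
    methods = tuple(columns.keys())
    vectors = [np.asarray(columns[m], dtype=float) for m in methods]
    if any(v.shape != (len(names),) for v in vectors):
        raise ValueError("all score vectors must match the number of features")
    matrix = np.column_stack(vectors) if methods else np.empty((len(names), 0))
    scores = matrix.sum(axis=1)
    order = np.lexsort((np.arange(len(names)), -scores))
    ranking = tuple(names[i] for i in order)
    return EnsembleResult(
        importance_matrix=ImportanceMatrix(names, methods, matrix),
        ensemble_scores=scores,
        ranking=ranking,
        selected=(),
    )


def select_features(
    result: EnsembleResult,
    rule: str = "above_mean",
    k: int | None = None,
    threshold: float | None = None,
) -> tuple[str, ...]:
    """Pick the feature subset from the ensemble scores.

    Rules: ``above_mean`` (default; strictly greater than the mean ensemble
    score), ``top_k`` (the k best-ranked), ``threshold`` (score strictly
    greater than t).  Deterministic; raises :class:`EmptySelectionError` when
    nothing qualifies.
    """
    names = result.feature_names
    scores = result.ensemble_scores
    if rule == "above_mean":
        chosen = tuple(n for n, s in zip(names, scores) if s > scores.mean())
    elif rule == "top_k":
        if k is None or not 1 <= k <= len(names):
            raise ValueError(f"top_k requires 1 <= k <= {len(names)}")
        chosen = result.ranking[:k]
    elif rule == "threshold":
        if threshold is None or not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold rule requires 0 <= t <= 1")
        chosen = tuple(n for n, s in zip(names, scores) if s > threshold)
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if not chosen:
        raise EmptySelectionError(
            f"selection rule {rule!r} returned no features; try top_k or a lower threshold"
        )
    return chosen


def _forest_seeds(config: RunConfig) -> dict[str, int | None]:
    """Per-variant seeds derived from the run seed, stable across selections."""
    if config.seed is None:
        return {m: None for m in FOREST_METHODS}
    children = np.random.SeedSequence(config.seed).spawn(len(FOREST_METHODS))
    return {
        m: int(c.generate_state(1)[0] % (2**31 - 1))
        for m, c in zip(FOREST_METHODS, children)
    }


def run_efs(table: FeatureTable, config: RunConfig | None = None) -> EnsembleResult:
    """The full ensemble feature-selection pipeline.

    NA-filter the table, run each selected scorer, normalize every raw vector
    to [0, 1/n] with n the number of selected methods, and aggregate.
    Deterministic given ``config.seed``; with only the deterministic scorers
    selected (median, pearson, spearman, logreg) the result is
    seed-independent.
    """
    config = config or RunConfig()
    filtered, report = filter_na(table, config.na_threshold)
    check_degenerate(filtered)
    methods = config.selected_methods
    seeds = _forest_seeds(config)
    raw: dict[str, RawScoreVector] = {}
    for m in methods:
        logger.info("scoring with %s", m)
        if m == "median":
            raw[m] = score_median(filtered)
        elif m in ("pearson", "spearman"):
            raw[m] = score_correlation(filtered, m, config.cor_threshold)
        elif m == "logreg":
            raw[m] = score_logreg(filtered)
        else:
            raw[m] = score_forest(
                filtered, m, runs=config.runs, seed=seeds[m], n_trees=config.n_trees
            )
    n = len(methods)
    columns = {m: normalize_scores(raw[m], n) for m in methods}
    result = aggregate_ensemble(columns, filtered.feature_names)
    try:
        selected = select_features(result)
    except EmptySelectionError:
        warnings.warn(
            "above-mean selection is empty (all ensemble scores equal); "
            "no features selected",
            EfsWarning,
            stacklevel=2,
        )
        selected = ()
    return dataclasses.replace(
        result, selected=selected, config_used=config, preprocess_report=report
    )
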