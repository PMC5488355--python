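"""The eight raw importance scorers.

Four families:

* ``median`` — two-sided Mann-Whitney U test between the class groups; the
  raw importance is 1 - p, so smaller p-values mean higher importance.
* ``pearson`` / ``spearman`` — feature-vs-class correlation p-values after a
  fast correlation-based filter (FCBF) has greedily eliminated features that
  are highly correlated with an already-kept, more class-correlated feature.
  Eliminated features score exactly 0.
* ``logreg`` — absolute standardized logistic-regression coefficients.
* ``rf_mdi`` / ``rf_error`` / ``cf_error`` / ``cf_auc`` — forest importances
  (Gini mean decrease impurity; OOB permutation importance on the error rate
  or the AUC), averaged over ``runs`` independently grown forests.

All scorers are pure functions of (table, parameters, seed) and assign their
minimum raw score to constant features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.exceptions import ConvergenceWarning

from .dataio import EfsWarning, FeatureTable
from .forest import ForestConfig, build_forest, importance_mdi, importance_permutation
from .preprocess import ztransform

__all__ = [
    "RawScoreVector",
    "score_median",
    "fcbf_eliminate",
    "score_correlation",
    "fit_logistic",
    "score_logreg",
    "score_forest",
]

#: Largest combined group size at which the Mann-Whitney p-value is computed by
#: exact enumeration (tie-free data only); beyond it the normal approximation
#: with tie and continuity correction is used.
EXACT_MW_LIMIT = 12

#: |beta| above which a penalty-free logistic fit is treated as separated.
SEPARATION_BETA_LIMIT = 15.0

#: Ridge penalty strength of the fallback fit (lambda on the standardized scale).
RIDGE_LAMBDA = 1e-4

FOREST_VARIANTS = ("rf_mdi", "rf_error", "cf_error", "cf_auc")


@dataclass(frozen=True)
class RawScoreVector:
    """One scorer's per-feature raw importances on its native scale."""

    method: str
    scores: np.ndarray
    eliminated: frozenset[str] = frozenset()


def score_median(table: FeatureTable) -> RawScoreVector:
    """Mann-Whitney importance: raw score 1 - p per feature.

    Pairwise-complete values are used.  A feature for which one class has no
    non-missing values scores 0 with a warning.
    """
    y = table.class_labels
    scores = np.zeros(table.n_features)
    for j, name in enumerate(table.feature_names):
        x = table.values[:, j]
        ok = ~np.isnan(x)
        a = x[ok & (y == 1)]
        b = x[ok & (y == 0)]
        if a.size == 0 or b.size == 0:
            warnings.warn(
                f"feature {name!r}: one class has no non-missing values; score 0",
                EfsWarning,
                stacklevel=2,
            )
            continue
        n = a.size + b.size
        has_ties = len(np.unique(np.concatenate([a, b]))) < n
        method = "exact" if (n <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        scores[j] = 1.0 - p
    return RawScoreVector("median", scores)


def _pairwise_abs_corr(x: np.ndarray, z: np.ndarray, method: str) -> float:
    """|correlation| on pairwise-complete pairs; 0 when undefined."""
    ok = ~(np.isnan(x) | np.isnan(z))
    if ok.sum() < 3:
        return 0.0
    xa, za = x[ok], z[ok]
    if np.all(xa == xa[0]) or np.all(za == za[0]):
        return 0.0
    if method == "pearson":
        r = stats.pearsonr(xa, za).statistic
    else:
        r = stats.spearmanr(xa, za).statistic
    return float(abs(r)) if np.isfinite(r) else 0.0


def fcbf_eliminate(
    table: FeatureTable, cor_threshold: float, method: str = "pearson"
) -> tuple[list[str], frozenset[str]]:
    """Greedy fast correlation-based filtering.

    Features are visited in order of decreasing |correlation with the class|
    (ties broken by input column order); a feature is kept iff its |pairwise
    correlation| with every already-kept feature stays at or below
    ``cor_threshold``.  Returns the kept features in visiting order and the
    eliminated set.
    """
    if not 0.0 < cor_threshold <= 1.0:
        raise ValueError("cor_threshold must be in (0, 1]")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    y = table.class_labels.astype(float)
    p = table.n_features
    class_corr = np.array(
        [_pairwise_abs_corr(table.values[:, j], y, method) for j in range(p)]
    )
    order = np.lexsort((np.arange(p), -class_corr))
    kept: list[int] = []
    for j in order:
        redundant = any(
            _pairwise_abs_corr(table.values[:, j], table.values[:, k], method) > cor_threshold
            for k in kept
        )
        if not redundant:
            kept.append(int(j))
    kept_names = [table.feature_names[j] for j in kept]
    eliminated = frozenset(set(table.feature_names) - set(kept_names))
    return kept_names, eliminated


def score_correlation(
    table: FeatureTable, method: str, cor_threshold: float
) -> RawScoreVector:
    """Correlation importance: 1 - p for kept features, exactly 0 for eliminated ones.

    The p-value is the two-sided test of the feature-vs-class correlation
    (Pearson product-moment or Spearman on average ranks) on pairwise-complete
    pairs.  Zero-variance features score 0 with a warning.
    """
    _, eliminated = fcbf_eliminate(table, cor_threshold, method)
    y = table.class_labels.astype(float)
    scores = np.zeros(table.n_features)
    for j, name in enumerate(table.feature_names):
        if name in eliminated:
            continue
        x = table.values[:, j]
        ok = ~np.isnan(x)
        xa, ya = x[ok], y[ok]
        if xa.size < 3 or np.all(xa == xa[0]):
            warnings.warn(
                f"feature {name!r}: correlation undefined (constant or too few values); score 0",
                EfsWarning,
                stacklevel=2,
            )
            continue
        if method == "pearson":
            p = stats.pearsonr(xa, ya).pvalue
        else:
            p = stats.spearmanr(xa, ya).pvalue
        scores[j] = 1.0 - p if np.isfinite(p) else 0.0
    return RawScoreVector(method, scores, eliminated)


def _ridge_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    clf = LogisticRegression(
        C=1.0 / (2.0 * RIDGE_LAMBDA), solver="lbfgs", max_iter=1000, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def fit_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic fit; returns (intercept, beta_1..beta_p).

    Expects standardized X with missing entries imputed to 0 (the column mean
    after standardization).  If p >= n, or the penalty-free fit shows signs of
    separation (any |beta| above 15 on the standardized scale), the model is
    refit with a small ridge penalty (lambda = 1e-4) and a warning is logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X = np.where(np.isnan(X), 0.0, X)
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature set")
    if p >= n:
        warnings.warn("p >= n: using ridge-penalized logistic fit", EfsWarning, stacklevel=2)
        return _ridge_fit(X, y)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=100, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    if np.any(np.abs(beta[1:]) > SEPARATION_BETA_LIMIT):
        warnings.warn(
            "separation detected in logistic fit: refitting with ridge penalty",
            EfsWarning,
            stacklevel=2,
        )
        return _ridge_fit(X, y)
    return beta


def score_logreg(table: FeatureTable) -> RawScoreVector:
    """Logistic-regression importance: |beta| of the Z-transformed fit."""
    Xz = ztransform(table.values)
    beta = fit_logistic(Xz, table.class_labels)
    return RawScoreVector("logreg", np.abs(beta[1:]))


def _impute_median(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        if nan.any():
            med = np.nanmedian(col) if not nan.all() else 0.0
            col[nan] = med if np.isfinite(med) else 0.0
    return out


def score_forest(
    table: FeatureTable,
    variant: str,
    runs: int,
    seed: int | None = None,
    n_trees: int = 100,
    mtry: int | None = None,
) -> RawScoreVector:
    """Forest importance averaged over ``runs`` independently grown forests.

    rf_* variants bag with replacement; cf_* variants subsample without
    replacement at fraction 0.632.  Missing values are median-imputed before
    tree growing.
    """
    if variant not in FOREST_VARIANTS:
        raise ValueError(f"unknown forest variant {variant!r}")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    X = _impute_median(table.values)
    y = table.class_labels
    sampling = "bootstrap" if variant.startswith("rf_") else "subsample"
    config = ForestConfig(n_trees=n_trees, mtry=mtry, sampling=sampling)
    children = np.random.SeedSequence(seed).spawn(runs)
    total = np.zeros(table.n_features)
    for child in children:
        rng = np.random.default_rng(child)
        forest = build_forest(X, y, config, rng)
        if variant == "rf_mdi":
            total += importance_mdi(forest, X, y)
        else:
            metric = "auc" if variant == "cf_auc" else "error"
            total += importance_permutation(forest, X, y, metric, rng)
    return RawScoreVector(variant, total / runs)
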