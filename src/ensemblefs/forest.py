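"""Random-forest machinery for the forest-based importance scorers.

Trees are CART classifiers (Gini splits, per-split random feature subsampling
of size mtry, grown to purity by default).  Each tree trains on either a
bootstrap-with-replacement sample (randomForest-style) or a without-replacement
subsample of fraction 0.632 (the cforest-approximation variants), and the
complementary out-of-bag (OOB) samples are recorded per tree for the
permutation importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .dataio import EfsWarning
from .metrics import classification_error, rank_auc

__all__ = ["ForestConfig", "Forest", "build_forest", "importance_mdi", "importance_permutation"]

#: Without-replacement subsample fraction for the cforest-approximation
#: variants; 0.632 matches the expected unique fraction of a bootstrap sample.
SUBSAMPLE_FRACTION = 0.632

# Cap on rows predicted per batched tree call, to bound the permuted-copy buffer.
_PREDICT_CHUNK_ROWS = 200_000


@dataclass
class ForestConfig:
    """Hyperparameters of a single forest.

    mtry defaults to floor(sqrt(p)); sampling is 'bootstrap' (with replacement,
    same size as the data) or 'subsample' (without replacement, fraction 0.632).
    """

    n_trees: int = 100
    mtry: int | None = None
    sampling: str = "bootstrap"
    subsample_fraction: float = SUBSAMPLE_FRACTION
    min_node: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.sampling not in ("bootstrap", "subsample"):
            raise ValueError("sampling must be 'bootstrap' or 'subsample'")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is None:
            return max(1, int(np.floor(np.sqrt(n_features))))
        if not 1 <= self.mtry <= n_features:
            raise ValueError(f"mtry must be in 1..{n_features}, got {self.mtry}")
        return self.mtry


@dataclass
class Forest:
    trees: list[DecisionTreeClassifier] = field(default_factory=list)
    oob_masks: list[np.ndarray] = field(default_factory=list)
    n_features: int = 0


def build_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig, rng: np.random.Generator) -> Forest:
    """Fit ``config.n_trees`` CART trees with per-tree resampling and OOB masks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    mtry = config.resolved_mtry(p)
    forest = Forest(n_features=p)
    for _ in range(config.n_trees):
        if config.sampling == "bootstrap":
            idx = rng.integers(0, n, size=n)
        else:
            k = max(2, int(np.ceil(config.subsample_fraction * n)))
            idx = rng.permutation(n)[:k]
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=config.min_node,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        forest.trees.append(tree)
        forest.oob_masks.append(oob)
    return forest


def _prob_class1(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    proba = tree.predict_proba(X)
    classes = list(tree.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(X.shape[0])


def importance_mdi(forest: Forest, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean decrease in Gini impurity, averaged over trees.

    Per tree this is the impurity decrease of each split weighted by the
    fraction of samples reaching the node, summed over nodes splitting on the
    feature; features never used by any split score 0.
    """
    total = np.zeros(forest.n_features)
    for tree in forest.trees:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.trees)


def importance_permutation(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    metric: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Breiman-style OOB permutation importance.

    For each tree and feature: evaluate the metric on the tree's OOB samples,
    permute that feature's OOB values once, re-evaluate.  Importance is the
    mean over trees of (permuted error - baseline error) for ``metric='error'``
    and (baseline AUC - permuted AUC) for ``metric='auc'``.  Negative averages
    are retained.  Trees whose OOB set is empty (or single-class when the AUC
    is requested) are skipped with a warning.
    """
    if metric not in ("error", "auc"):
        raise ValueError("metric must be 'error' or 'auc'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = forest.n_features
    diffs = np.zeros(p)
    n_used = 0
    n_skipped = 0
    for tree, oob in zip(forest.trees, forest.oob_masks):
        X_o = X[oob]
        y_o = y[oob]
        if len(y_o) == 0 or (metric == "auc" and len(np.unique(y_o)) < 2):
            n_skipped += 1
            continue
        if metric == "auc":
            baseline = rank_auc(_prob_class1(tree, X_o), y_o)
        else:
            baseline = classification_error(tree.predict(X_o), y_o)

        n_o = len(y_o)
        chunk = max(1, _PREDICT_CHUNK_ROWS // max(1, n_o))
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            big = np.repeat(X_o[None, :, :], len(feats), axis=0)
            for i, j in enumerate(feats):
                big[i, :, j] = rng.permutation(X_o[:, j])
            flat = big.reshape(-1, p)
            if metric == "auc":
                scores = _prob_class1(tree, flat).reshape(len(feats), n_o)
                for i, j in enumerate(feats):
                    diffs[j] += baseline - rank_auc(scores[i], y_o)
            else:
                preds = tree.predict(flat).reshape(len(feats), n_o)
                for i, j in enumerate(feats):
                    diffs[j] += classification_error(preds[i], y_o) - baseline
        n_used += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} tree(s) skipped (empty or single-class OOB set)",
            EfsWarning,
            stacklevel=2,
        )
    if n_used == 0:
        warnings.warn("no usable OOB sets; permutation importance is all zero", EfsWarning, stacklevel=2)
        return diffs
    return diffs / n_used
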