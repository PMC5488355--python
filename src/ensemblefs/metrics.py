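"""Small shared metrics: rank-based AUC and classification error."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["rank_auc", "classification_error"]


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formula with midrank tie handling.

    Equals U / (n1 * n0): the probability that a random positive outranks a
    random negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_error(predicted: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.asarray(predicted) != np.asarray(labels)))
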