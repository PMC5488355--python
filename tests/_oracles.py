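"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every label assignment of the combined sample; the AUC oracle
counts positive-negative pairs directly.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def mw_exact_p_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by exhaustive enumeration.

    Enumerates all C(n, n_a) assignments of the pooled values to the first
    group, builds the permutation distribution of U, and returns
    min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).
    """
    combined = np.concatenate([a, b])
    na = len(a)
    ranks = rankdata(combined)

    def u_of(indices) -> float:
        return ranks[list(indices)].sum() - na * (na + 1) / 2.0

    observed = u_of(range(na))
    us = np.array([u_of(c) for c in itertools.combinations(range(len(combined)), na)])
    p_le = np.mean(us <= observed)
    p_ge = np.mean(us >= observed)
    return min(1.0, 2.0 * min(p_le, p_ge))


def auc_paircount(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by direct enumeration of positive-negative pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
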