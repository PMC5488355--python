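"""Evaluation suite for an ensemble feature-selection result.

Four tests, individually switchable:

* **logreg** — LOOCV logistic-regression performance of the selected features
  versus all features, compared on their ROC curves with DeLong's test for
  paired AUCs.
* **permutation** — class labels permuted ``p_num`` times; the permuted-label
  LOOCV AUCs are compared against the observed AUC with a one-sided
  one-sample t-test (small p: the model beats chance).
* **variances** — stability of the importances under repeated stratified
  subsampling (``bs_num`` rounds of ``bs_percentage`` of the samples without
  replacement); per-feature variances of the ensemble scores are reported.
* **jaccard** — stability of the *selected subsets* across the same
  subsampling rounds, measured as |S1 ∩ … ∩ Sn| / |S1 ∪ … ∪ Sn|.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataio import EfsWarning, FeatureTable, RunConfig
from .ensemble import EmptySelectionError, EnsembleResult, run_efs, select_features
from .scorers import fit_logistic

__all__ = [
    "RocCurve",
    "EvalReport",
    "roc_auc",
    "loocv_lr",
    "delong_test",
    "permutation_test",
    "bootstrap_importances",
    "jaccard_index",
    "efs_eval",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and its area; midrank convention for tied scores.

    The stored AUC is the trapezoidal integral of the curve, which equals the
    rank-statistic form U/(n1*n0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def _zfit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means/sds of the training fold; zero-variance columns flagged."""
    mu = np.nanmean(train, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(train, axis=0, ddof=1)
    degenerate = ~np.isfinite(sd) | (sd == 0)
    sd = np.where(degenerate, 1.0, sd)
    mu = np.where(np.isfinite(mu), mu, 0.0)
    return mu, sd, degenerate


def _zapply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray, degenerate: np.ndarray) -> np.ndarray:
    Z = (X - mu) / sd
    Z[:, degenerate] = 0.0
    return np.where(np.isnan(Z), 0.0, Z)


def loocv_lr(table: FeatureTable, features: Sequence[str]) -> np.ndarray:
    """Leave-one-out logistic-regression scores, one per sample.

    Each fold standardizes on the training samples only (no leakage) and
    predicts the held-out sample's class-1 probability.  A training fold with
    a single class predicts the training class rate, with a warning.
    """
    if len(features) == 0:
        raise ValueError("feature subset must be non-empty")
    if table.n_samples < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    sub = table.subset_features(list(features))
    X = sub.values
    y = sub.class_labels
    n = table.n_samples
    out = np.empty(n)
    warned = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            if not warned:
                warnings.warn(
                    "single-class training fold in LOOCV; predicting the class rate",
                    EfsWarning,
                    stacklevel=2,
                )
                warned = True
            out[i] = float(ytr.mean())
            continue
        mu, sd, degen = _zfit(X[mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EfsWarning)
            beta = fit_logistic(_zapply(X[mask], mu, sd, degen), ytr)
        xi = _zapply(X[i : i + 1], mu, sd, degen)[0]
        eta = beta[0] + xi @ beta[1:]
        out[i] = 1.0 / (1.0 + np.exp(-eta))
    return out


def _structural_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong structural components via midranks (Sun & Xu formulation)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """Two-sided DeLong test for paired AUCs on the same samples.

    Returns the p-value for H0: AUC_a = AUC_b under the asymptotic normal
    reference, using the structural-component covariance estimate.  A zero
    variance of the AUC difference (e.g. identical score vectors) yields p = 1
    by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("score vectors and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _structural_components(a, labels)
    auc_b, v10_b, v01_b = _structural_components(b, labels)
    m, n = len(v10_a), len(v01_a)
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    if var <= 0 or not np.isfinite(var):
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class PermutationResult:
    observed_auc: float
    perm_aucs: np.ndarray
    perm_p: float


def permutation_test(
    table: FeatureTable,
    features: Sequence[str],
    p_num: int = 100,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Class-permutation robustness test of the LOOCV logistic model.

    The labels are permuted ``p_num`` times; each time the LOOCV AUC on the
    fixed feature subset is recorded.  ``perm_p`` is the one-sided one-sample
    t-test p-value of H0: mean(perm AUCs) >= observed AUC — small values mean
    the observed model beats chance.
    """
    if p_num < 2:
        raise ValueError("p_num must be >= 2")
    rng = rng or np.random.default_rng()
    y = table.class_labels
    observed = roc_auc(loocv_lr(table, features), y).auc
    perm_aucs = np.empty(p_num)
    for i in range(p_num):
        permuted = FeatureTable(
            table.feature_names, table.values, rng.permutation(y), table.class_column_ref
        )
        perm_aucs[i] = roc_auc(loocv_lr(permuted, features), permuted.class_labels).auc
    if perm_aucs.std(ddof=1) == 0.0:
        perm_p = 1.0 if perm_aucs.mean() >= observed else 0.0
    else:
        perm_p = float(
            stats.ttest_1samp(perm_aucs, observed, alternative="less").pvalue
        )
    return PermutationResult(observed_auc=observed, perm_aucs=perm_aucs, perm_p=perm_p)


@dataclass(frozen=True)
class BootstrapResult:
    scores: pd.DataFrame  # rounds x features, ensemble scores
    variances: pd.Series  # per-feature sample variance across rounds
    subsets: tuple[frozenset[str], ...]


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a without-replacement subsample keeping both classes."""
    n = len(y)
    k = int(np.floor(fraction * n))
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if fraction >= 1.0:
        return np.arange(n)
    k1 = int(round(k * len(idx1) / n))
    k1 = min(max(k1, 1), len(idx1), k - 1)
    k0 = min(k - k1, len(idx0))
    take = np.concatenate(
        [rng.choice(idx1, size=k1, replace=False), rng.choice(idx0, size=k0, replace=False)]
    )
    return np.sort(take)


def bootstrap_importances(
    table: FeatureTable,
    config: RunConfig,
    bs_num: int = 100,
    bs_percentage: float = 0.9,
    rng: np.random.Generator | None = None,
    selection_rule: str = "above_mean",
) -> BootstrapResult:
    """Importance stability under repeated stratified subsampling.

    Each of ``bs_num`` rounds draws floor(bs_percentage * n) samples without
    replacement (stratified so both classes survive), reruns the full ensemble
    and records the ensemble scores and the selected subset.  Features dropped
    by a round's NA filter contribute a score of 0 for that round.
    """
    if not 0.0 < bs_percentage <= 1.0:
        raise ValueError("bs_percentage must be in (0, 1]")
    if bs_num < 2:
        raise ValueError("bs_num must be >= 2")
    rng = rng or np.random.default_rng()
    rows = []
    subsets = []
    for _ in range(bs_num):
        idx = _stratified_subsample(table.class_labels, bs_percentage, rng)
        sub = table.subset_samples(idx)
        round_cfg = config.replace(seed=int(rng.integers(0, 2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EfsWarning)
            result = run_efs(sub, round_cfg)
        rows.append(result.scores_by_name())
        subsets.append(frozenset(result.selected))
    scores = pd.DataFrame(rows, columns=list(table.feature_names)).fillna(0.0)
    # shift by the first round before the variance: mathematically a no-op,
    # numerically exact (0) when every round produced identical scores
    variances = (scores - scores.iloc[0]).var(axis=0, ddof=1)
    return BootstrapResult(scores=scores, variances=variances, subsets=tuple(subsets))


def jaccard_index(subsets: Iterable[Iterable[str]]) -> float:
    """Stability of feature subsets: |S1 ∩ … ∩ Sn| / |S1 ∪ … ∪ Sn|.

    1 means all subsets are identical; 0 means no feature is common to all.
    """
    sets = [set(s) for s in subsets]
    if not sets:
        raise ValueError("need at least one subset")
    union = set().union(*sets)
    if not union:
        raise ValueError("Jaccard index undefined: all subsets are empty")
    inter = set.intersection(*sets)
    return len(inter) / len(union)


@dataclass
class EvalReport:
    """Results of the flagged evaluation tests; unrun tests stay None."""

    selected_features: tuple[str, ...] = ()
    auc_selected: float | None = None
    auc_all: float | None = None
    delong_p: float | None = None
    roc_selected: RocCurve | None = None
    roc_all: RocCurve | None = None
    observed_auc: float | None = None
    perm_aucs: np.ndarray | None = None
    perm_p: float | None = None
    importance_variances: dict[str, float] | None = None
    bootstrap_scores: pd.DataFrame | None = None
    bootstrap_subsets: tuple[frozenset[str], ...] | None = None
    jaccard: float | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, pd.DataFrame):
                return {c: v[c].tolist() for c in v.columns}
            if isinstance(v, tuple) and v and isinstance(v[0], frozenset):
                return [sorted(s) for s in v]
            return v

        out = {
            "selected_features": list(self.selected_features),
            "auc_selected": self.auc_selected,
            "auc_all": self.auc_all,
            "delong_p": self.delong_p,
            "observed_auc": self.observed_auc,
            "perm_aucs": conv(self.perm_aucs),
            "perm_p": self.perm_p,
            "importance_variances": self.importance_variances,
            "bootstrap_scores": conv(self.bootstrap_scores),
            "bootstrap_subsets": conv(self.bootstrap_subsets),
            "jaccard": self.jaccard,
        }
        return {k: v for k, v in out.items() if v is not None}

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def efs_eval(
    table: FeatureTable,
    efs_result: EnsembleResult,
    logreg: bool = True,
    permutation: bool = False,
    variances: bool = False,
    jaccard: bool = False,
    p_num: int = 100,
    bs_num: int = 100,
    bs_percentage: float = 0.9,
    seed: int | None = None,
    selection_rule: str = "above_mean",
    top_k: int | None = None,
) -> EvalReport:
    """Run the flagged evaluation tests on an ensemble result.

    The Jaccard index is computed from the subsets produced by the
    subsampling rounds, so ``jaccard=True`` forces the bootstrap to run even
    if ``variances`` is off.  Deterministic given ``seed``.
    """
    if not (logreg or permutation or variances or jaccard):
        raise ValueError("no evaluation selected: enable at least one test")
    if jaccard and bs_num < 2:
        raise ValueError("jaccard requires bs_num >= 2")
    features = efs_result.selected
    if selection_rule != "above_mean" or top_k is not None:
        features = select_features(
            efs_result, rule="top_k" if top_k else selection_rule, k=top_k
        )
    if not features:
        raise EmptySelectionError("no selected features to evaluate; choose a selection rule")
    ss = np.random.SeedSequence(seed)
    perm_ss, bs_ss = ss.spawn(2)
    report = EvalReport(selected_features=tuple(features))

    if logreg:
        y = table.class_labels
        scores_sel = loocv_lr(table, features)
        scores_all = loocv_lr(table, table.feature_names)
        report.roc_selected = roc_auc(scores_sel, y)
        report.roc_all = roc_auc(scores_all, y)
        report.auc_selected = report.roc_selected.auc
        report.auc_all = report.roc_all.auc
        report.delong_p = delong_test(scores_all, scores_sel, y)

    if permutation:
        pr = permutation_test(
            table, features, p_num=p_num, rng=np.random.default_rng(perm_ss)
        )
        report.observed_auc = pr.observed_auc
        report.perm_aucs = pr.perm_aucs
        report.perm_p = pr.perm_p

    if variances or jaccard:
        config = efs_result.config_used or RunConfig()
        br = bootstrap_importances(
            table,
            config,
            bs_num=bs_num,
            bs_percentage=bs_percentage,
            rng=np.random.default_rng(bs_ss),
        )
        report.bootstrap_subsets = br.subsets
        if variances:
            report.importance_variances = {
                k: float(v) for k, v in br.variances.items()
            }
            report.bootstrap_scores = br.scores
        if jaccard:
            nonempty = [s for s in br.subsets if s]
            if not nonempty:
                raise ValueError("Jaccard index undefined: every round selected nothing")
            report.jaccard = jaccard_index(br.subsets)
    return report
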