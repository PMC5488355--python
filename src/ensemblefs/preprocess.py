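"""Cleaning the feature table before scoring.

High-NA features are removed up front; remaining missing values are handled
per scorer (pairwise-complete deletion for rank/correlation tests, median
imputation inside the forests).  Z-transformation is applied only where the
logistic-regression scorer needs it, not globally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import EfsWarning, FeatureTable

__all__ = ["PreprocessReport", "filter_na", "ztransform", "check_degenerate"]

logger = logging.getLogger(__name__)

#: Minority-class fraction below which an imbalance warning is emitted
#: (Gini-based importances are known to be unstable on unbalanced data).
IMBALANCE_WARN_FRACTION = 0.10


@dataclass
class PreprocessReport:
    removed_na_features: list[tuple[str, float]] = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)
    n_kept: int = 0
    imbalance_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "removed_na_features": [
                {"name": n, "na_fraction": f} for n, f in self.removed_na_features
            ],
            "constant_features": list(self.constant_features),
            "n_kept": self.n_kept,
            "imbalance_warning": self.imbalance_warning,
        }


def filter_na(table: FeatureTable, na_threshold: float) -> tuple[FeatureTable, PreprocessReport]:
    """Drop features whose missing fraction is *strictly greater* than the threshold.

    The boundary case (fraction exactly equal to the threshold) is kept.
    Remaining missing entries stay in place for the scorers to handle.
    """
    if not 0.0 <= na_threshold <= 1.0:
        raise ValueError("na_threshold must be in [0, 1]")
    frac = np.isnan(table.values).mean(axis=0)
    keep = frac <= na_threshold
    report = PreprocessReport(
        removed_na_features=[
            (name, float(f))
            for name, f, k in zip(table.feature_names, frac, keep)
            if not k
        ],
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        raise ValueError("no features remain after NA filtering")
    kept_names = [n for n, k in zip(table.feature_names, keep) if k]
    filtered = table.subset_features(kept_names)
    if report.removed_na_features:
        logger.info(
            "NA filter removed %d feature(s): %s",
            len(report.removed_na_features),
            [n for n, _ in report.removed_na_features],
        )
    return filtered, report


def ztransform(values: np.ndarray) -> np.ndarray:
    """Column-wise standardization to mean 0, sd 1 (n-1 denominator), NaN-aware.

    Zero-variance columns map to all-zero columns; missing entries stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 2:
            raise ValueError(f"column {j} has fewer than 2 non-missing values")
        mu = col[ok].mean()
        sd = col[ok].std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            out[:, j] = np.where(ok, 0.0, np.nan)
        else:
            out[:, j] = (col - mu) / sd
    return out


def check_degenerate(table: FeatureTable) -> PreprocessReport:
    """Flag constant features and strong class imbalance.

    Constant features receive the minimum raw importance from every scorer;
    they are reported rather than removed.  A minority-class fraction below
    10% triggers a logged warning.
    """
    report = PreprocessReport(n_kept=table.n_features)
    for j, name in enumerate(table.feature_names):
        col = table.values[:, j]
        ok = ~np.isnan(col)
        if ok.sum() == 0 or np.all(col[ok] == col[ok][0]):
            report.constant_features.append(name)
    if report.constant_features:
        warnings.warn(
            f"constant feature(s) will score at the importance floor: "
            f"{report.constant_features}",
            EfsWarning,
            stacklevel=2,
        )
    minority = min(table.class_labels.mean(), 1.0 - table.class_labels.mean())
    if minority < IMBALANCE_WARN_FRACTION:
        report.imbalance_warning = True
        logger.warning(
            "strong class imbalance (minority fraction %.3f): Gini-based "
            "importances may be unstable",
            minority,
        )
    return report
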