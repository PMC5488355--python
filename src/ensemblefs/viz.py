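"""Figures: cumulative importance barplot, ROC comparison, bootstrap boxplots.

Every plot writes a JSON sidecar (same basename, ``.json``) carrying the
plotted values, so figures are assertable in tests without image parsing.
PDF is the default format; PNG and SVG work through the file suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .ensemble import EnsembleResult
from .evaluation import RocCurve

__all__ = ["cumulative_barplot", "roc_plot", "variance_boxplot"]

_FORMATS = (".pdf", ".png", ".svg")

_METHOD_COLORS = {
    "median": "#1b9e77",
    "pearson": "#d95f02",
    "spearman": "#7570b3",
    "logreg": "#e7298a",
    "rf_mdi": "#66a61e",
    "rf_error": "#e6ab02",
    "cf_error": "#a6761d",
    "cf_auc": "#666666",
}


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported format {path.suffix!r}; use one of {_FORMATS}")
    return path


def _sidecar(path: Path, payload: dict) -> Path:
    side = path.with_suffix(".json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return side


def cumulative_barplot(result: EnsembleResult, path: str | Path, title: str | None = None) -> Path:
    """Stacked bar per feature: segment heights are the normalized per-method
    scores, total bar height is the ensemble score; features ordered by
    decreasing ensemble score."""
    path = _check_path(path)
    mat = result.importance_matrix
    if len(mat.feature_names) == 0:
        raise ValueError("no features to plot")
    frame = mat.to_frame().loc[list(result.ranking)]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(frame)), 4.5))
    bottom = pd.Series(0.0, index=frame.index)
    for method in frame.columns:
        ax.bar(
            frame.index,
            frame[method],
            bottom=bottom,
            label=method,
            color=_METHOD_COLORS.get(method),
        )
        bottom += frame[method]
    ax.set_ylabel("ensemble importance")
    ax.set_ylim(0, 1)
    ax.set_title(title or "Cumulative feature importances")
    ax.legend(fontsize="small")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    _sidecar(
        path,
        {
            "order": list(frame.index),
            "segments": {m: frame[m].tolist() for m in frame.columns},
            "ensemble": bottom.tolist(),
        },
    )
    return path


def roc_plot(
    curve_all: RocCurve,
    curve_selected: RocCurve,
    delong_p: float,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """ROC curves of the all-features and selected-features models.

    Sensitivity vs 1-specificity; the dotted diagonal marks random guessing;
    the annotation carries both AUCs and the DeLong p-value.
    """
    path = _check_path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve_all.fpr, curve_all.tpr, color="black", label=f"all features (AUC={curve_all.auc:.3g})")
    ax.plot(
        curve_selected.fpr,
        curve_selected.tpr,
        color="tab:blue",
        label=f"selected features (AUC={curve_selected.auc:.3g})",
    )
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(title or f"LOOCV ROC comparison (DeLong p = {delong_p:.3g})")
    ax.legend(loc="lower right", fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    _sidecar(
        path,
        {
            "auc_all": curve_all.auc,
            "auc_selected": curve_selected.auc,
            "delong_p": float(delong_p),
            "fpr_all": curve_all.fpr.tolist(),
            "tpr_all": curve_all.tpr.tolist(),
            "fpr_selected": curve_selected.fpr.tolist(),
            "tpr_selected": curve_selected.tpr.tolist(),
        },
    )
    return path


def variance_boxplot(
    distributions: pd.DataFrame,
    path: str | Path,
    order: list[str] | None = None,
    title: str | None = None,
) -> Path:
    """One box per feature over its bootstrap score distribution.

    ``distributions`` is rounds x features; boxes use the 1.5 IQR whisker
    convention with outliers as points.
    """
    path = _check_path(path)
    if distributions.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap rounds")
    cols = order or list(distributions.columns)
    data = [distributions[c].to_numpy() for c in cols]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(cols)), 4.5))
    ax.boxplot(data, tick_labels=cols, whis=1.5)
    ax.set_ylabel("ensemble importance")
    ax.set_title(title or "Bootstrap importance distributions")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize="small")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    _sidecar(
        path,
        {
            "order": cols,
            "medians": {c: float(distributions[c].median()) for c in cols},
            "variances": {c: float(distributions[c].var(ddof=1)) for c in cols},
        },
    )
    return path
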