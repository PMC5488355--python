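"""Reading feature tables, run configuration, and importance-table round-tripping.

The universal input is a delimited text table (comma, tab or semicolon) of
samples x features with one binary class column coded 0/1.  Categorical
features must arrive dummy-encoded; any non-numeric, non-missing cell in a
feature column is an error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "METHOD_NAMES",
    "DEFAULT_NA_TOKENS",
    "FeatureTable",
    "RunConfig",
    "read_table",
    "write_importance_table",
    "read_importance_table",
    "load_config",
]

#: Canonical method order used everywhere a selection is iterated.
METHOD_NAMES = (
    "median",
    "pearson",
    "spearman",
    "logreg",
    "rf_mdi",
    "rf_error",
    "cf_error",
    "cf_auc",
)

DEFAULT_NA_TOKENS = ("NA", "NaN", "")


class EfsWarning(UserWarning):
    """Data-quality warnings raised while scoring or preprocessing."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x named numeric features plus a binary class vector.

    ``values`` is an (n_samples, n_features) float array with ``nan`` marking
    missing entries.  ``class_labels`` holds 0/1 integers; both classes must
    occur.  ``class_column_ref`` remembers how the class column was addressed
    in the source file (1-based index or header name).
    """

    feature_names: tuple[str, ...]
    values: np.ndarray
    class_labels: np.ndarray
    class_column_ref: int | str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.class_labels)
        object.__setattr__(self, "feature_names", tuple(str(n) for n in self.feature_names))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.feature_names) != values.shape[1]:
            raise ValueError("feature_names length must match number of value columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if labels.ndim != 1 or labels.shape[0] != values.shape[0]:
            raise ValueError("class_labels length must match number of rows")
        uniq = set(np.unique(labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"class not binary: found values {sorted(uniq - {0, 1})}")
        if uniq != {0, 1}:
            raise ValueError("both classes (0 and 1) must occur at least once")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "class_labels", labels.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: np.ndarray) -> "FeatureTable":
        """Row subset (labels kept aligned)."""
        return FeatureTable(
            self.feature_names,
            self.values[index],
            self.class_labels[index],
            self.class_column_ref,
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        pos = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        cols = [pos[n] for n in names]
        return FeatureTable(
            tuple(names), self.values[:, cols], self.class_labels, self.class_column_ref
        )

    def to_frame(self, class_name: str = "class") -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame.insert(0, class_name, self.class_labels)
        return frame


def _default_selection() -> dict[str, bool]:
    # cforest-style variants are off by default (costly); the other six are on.
    return {m: m not in ("cf_error", "cf_auc") for m in METHOD_NAMES}


@dataclass
class RunConfig:
    """Parameters of an ensemble feature-selection run.

    na_threshold : max tolerated fraction of missing values per feature (strict:
        a feature is dropped when its NA fraction exceeds this). Default 0.2.
    cor_threshold : feature-to-feature correlation ceiling for the fast
        correlation-based filter. Default 0.7.
    runs : number of independent forests averaged per forest scorer. Default 100.
    selection : which of the eight scorers participate.
    n_trees : trees per forest (per run).
    """

    na_threshold: float = 0.2
    cor_threshold: float = 0.7
    runs: int = 100
    selection: dict[str, bool] = field(default_factory=_default_selection)
    n_trees: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.na_threshold <= 1.0:
            raise ValueError("na_threshold must be in [0, 1]")
        if not 0.0 < self.cor_threshold <= 1.0:
            raise ValueError("cor_threshold must be in (0, 1]")
        if self.runs < 1:
            raise ValueError("runs must be a positive integer")
        if self.n_trees < 1:
            raise ValueError("n_trees must be a positive integer")
        unknown = set(self.selection) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown methods in selection: {sorted(unknown)}")
        full = _default_selection()
        full.update(self.selection)
        self.selection = full
        if not any(self.selection.values()):
            raise ValueError("at least one selection flag must be true")

    @property
    def selected_methods(self) -> tuple[str, ...]:
        return tuple(m for m in METHOD_NAMES if self.selection[m])

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "na_threshold": self.na_threshold,
            "cor_threshold": self.cor_threshold,
            "runs": self.runs,
            "selection": dict(self.selection),
            "n_trees": self.n_trees,
            "seed": self.seed,
        }


def _sniff_delimiter(header: str) -> str:
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError("could not detect delimiter (expected comma, tab or semicolon)")
    return best


def read_table(
    path: str | Path,
    class_ref: int | str,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> FeatureTable:
    """Read a delimited samples-x-features table and split off the class column.

    ``class_ref`` is either a 1-based column index (counting every column of
    the file, as R users would) or a header name.  Cells matching one of
    ``na_tokens`` become missing values; any other non-numeric cell in a
    feature column is an error (categorical variables must be dummy-encoded
    beforehand).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True)

    if isinstance(class_ref, (int, np.integer)) and not isinstance(class_ref, bool):
        if not 1 <= int(class_ref) <= frame.shape[1]:
            raise ValueError(
                f"class column index {class_ref} out of range 1..{frame.shape[1]} (1-based)"
            )
        class_name = frame.columns[int(class_ref) - 1]
    else:
        class_name = str(class_ref)
        if class_name not in frame.columns:
            raise ValueError(f"class column {class_name!r} not found in header")

    na_set = {t.strip() for t in na_tokens}

    def parse_column(col: pd.Series, name: str) -> np.ndarray:
        raw = col.str.strip()
        is_na = raw.isin(na_set)
        numeric = pd.to_numeric(raw.where(~is_na), errors="coerce")
        bad = (~is_na) & numeric.isna()
        if bad.any():
            tokens = sorted(raw[bad].unique().tolist())[:5]
            raise ValueError(
                f"feature column {name!r} contains non-numeric values {tokens}; "
                "categorical variables must be transformed to dummy variables in advance"
            )
        return numeric.to_numpy(dtype=float)

    raw_class = frame[class_name].str.strip()
    if raw_class.isin(na_set).any():
        raise ValueError("class column contains missing values; remove those rows first")
    class_numeric = pd.to_numeric(raw_class, errors="coerce")
    offending = sorted(raw_class[(class_numeric.isna()) | (~class_numeric.isin([0, 1]))].unique())
    if offending:
        raise ValueError(f"class not binary: offending values {offending}")

    feature_cols = [c for c in frame.columns if c != class_name]
    values = np.column_stack([parse_column(frame[c], c) for c in feature_cols]) if feature_cols else np.empty((len(frame), 0))
    return FeatureTable(
        tuple(feature_cols),
        values,
        class_numeric.to_numpy(dtype=np.int64),
        class_ref if isinstance(class_ref, str) else int(class_ref),
    )


def write_importance_table(result, path: str | Path) -> Path:
    """Serialize an :class:`~ensemblefs.ensemble.EnsembleResult` as TSV.

    One row per feature, one column per selected method plus the ``ensemble``
    sum; values round-trip losslessly at 12 significant digits.
    """
    mat = result.importance_matrix
    if len(mat.methods) == 0 or len(mat.feature_names) == 0:
        raise ValueError("cannot write an empty importance table")
    frame = mat.to_frame()
    frame["ensemble"] = result.ensemble_scores
    path = Path(path)
    frame.to_csv(path, sep="\t", index_label="feature", float_format="%.12g")
    return path


def read_importance_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_importance_table`."""
    frame = pd.read_csv(path, sep="\t", index_col="feature")
    if frame.shape[0] == 0 or "ensemble" not in frame.columns:
        raise ValueError(f"{path} is not a valid importance table")
    return frame


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data: Mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a mapping")
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
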