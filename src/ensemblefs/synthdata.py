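"""Synthetic binary-classification tables with controlled signal.

The generator emulates the shape of the tables the selector expects: a 0/1
class column plus numeric features, with three feature roles —

* *informative*: standard Gaussian plus a mean shift of ``effect_size``
  standard deviations for class-1 samples;
* *correlated*: rho-correlated copies of informative parents
  (rho * parent + sqrt(1 - rho^2) * noise), signal inherited via the parent;
* *noise*: independent standard Gaussians.

Missing values are injected completely at random at rate ``na_rate``.
A ground-truth sidecar names each feature's role and parent so recovery can
be asserted in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import FeatureTable

__all__ = ["SyntheticSpec", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_samples: int = 100
    class_balance: float = 0.5
    n_informative: int = 5
    effect_size: float = 1.5
    n_correlated: int = 0
    rho: float = 0.8
    n_noise: int = 20
    na_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if min(self.n_informative, self.n_correlated, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_informative + self.n_correlated + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if abs(self.rho) > 1.0:
            raise ValueError("|rho| must be <= 1")
        if not 0.0 <= self.na_rate < 1.0:
            raise ValueError("na_rate must be in [0, 1)")
        if self.n_correlated > 0 and self.n_informative == 0:
            raise ValueError("correlated features need informative parents")


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, dict[str, dict]]:
    """Draw a table and its ground truth; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    for _ in range(100):
        labels = (rng.random(n) < spec.class_balance).astype(np.int64)
        if 0 < labels.sum() < n:
            break
    else:
        raise ValueError("could not draw both classes; adjust class_balance or n_samples")

    names: list[str] = []
    cols: list[np.ndarray] = []
    truth: dict[str, dict] = {}

    informative = []
    for i in range(spec.n_informative):
        name = f"inf_{i + 1}"
        col = rng.standard_normal(n) + spec.effect_size * labels
        names.append(name)
        cols.append(col)
        informative.append((name, col))
        truth[name] = {"role": "informative", "parent": None, "effect_size": spec.effect_size}
    for i in range(spec.n_correlated):
        parent_name, parent = informative[i % len(informative)]
        name = f"cor_{i + 1}"
        col = spec.rho * parent + np.sqrt(1.0 - spec.rho**2) * rng.standard_normal(n)
        names.append(name)
        cols.append(col)
        truth[name] = {"role": "correlated", "parent": parent_name, "rho": spec.rho}
    for i in range(spec.n_noise):
        name = f"noise_{i + 1}"
        names.append(name)
        cols.append(rng.standard_normal(n))
        truth[name] = {"role": "noise", "parent": None}

    values = np.column_stack(cols)
    if spec.na_rate > 0:
        mask = rng.random(values.shape) < spec.na_rate
        values = np.where(mask, np.nan, values)
    return FeatureTable(tuple(names), values, labels), truth


def write_fixture(
    table: FeatureTable,
    ground_truth: dict[str, dict],
    directory: str | Path,
    name: str = "synthetic",
) -> tuple[Path, Path]:
    """Write the CSV (class column first) and the ground-truth JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{name}.csv"
    truth_path = directory / f"{name}_truth.json"
    frame = table.to_frame(class_name="class")
    frame.to_csv(csv_path, index=False, na_rep="NA", float_format="%.12g")
    truth_path.write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
    return csv_path, truth_path
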