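import numpy as np
import pytest

from ensemblefs import FeatureTable, RunConfig, SyntheticSpec, generate


@pytest.fixture
def tiny_table() -> FeatureTable:
    """Six samples, three features: one separating, one noisy, one constant."""
    values = np.array(
        [
            [0.1, 5.0, 2.0],
            [0.2, 3.0, 2.0],
            [0.3, 4.0, 2.0],
            [1.1, 4.5, 2.0],
            [1.2, 2.5, 2.0],
            [1.3, 5.5, 2.0],
        ]
    )
    labels = np.array([0, 0, 0, 1, 1, 1])
    return FeatureTable(("sep", "noisy", "const"), values, labels)


@pytest.fixture
def informative_table() -> FeatureTable:
    """n=80 with 3 informative (2 sd shift) and 10 noise features."""
    table, _ = generate(
        SyntheticSpec(n_samples=80, n_informative=3, effect_size=2.0, n_noise=10, seed=11)
    )
    return table


@pytest.fixture
def fast_config() -> RunConfig:
    return RunConfig(runs=2, n_trees=25, seed=123)


@pytest.fixture
def deterministic_config() -> RunConfig:
    """Only the seed-free scorers."""
    return RunConfig(
        selection={
            "median": True,
            "pearson": True,
            "spearman": True,
            "logreg": True,
            "rf_mdi": False,
            "rf_error": False,
            "cf_error": False,
            "cf_auc": False,
        }
    )
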