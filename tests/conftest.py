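import numpy as np
import pytest

from fsgp.data_model import FeatureTable
from fsgp.gp_core import FSGPConfig


@pytest.fixture
def toy_table() -> FeatureTable:
    """5 samples x 3 features, hand-enumerable."""
    values = np.array([
        [1.0, 0.5, -0.2],
        [0.2, 0.9, 0.1],
        [-0.5, -1.0, 0.3],
        [0.0, 0.0, -0.4],
        [2.0, 1.0, 0.8],
    ])
    labels = np.array([1, 0, 1, 1, 0])
    return FeatureTable(["f1", "f2", "f3"], values, labels)


@pytest.fixture
def small_config() -> FSGPConfig:
    """A light configuration for fast evolutionary runs in tests."""
    return FSGPConfig(
        population_size=20,
        init_min_depth=2,
        init_max_depth=4,
        max_tree_depth=8,
        tournament_size=3,
        evaluation_budget=2000,
        hc_max_retries=3,
        seed=0,
    )


def random_tree_strategy_config() -> FSGPConfig:
    return FSGPConfig(init_min_depth=1, init_max_depth=6, max_tree_depth=10)
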