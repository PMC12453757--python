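import numpy as np
import pytest

from psonet.preprocess import FeatureTable
from psonet.synthetic_data import SyntheticSpec, generate_voice_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """60-row, 4-feature table with a clear class signal."""
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 4))
    X[y == 1] += 1.5
    return FeatureTable(X, ["f1", "f2", "f3", "f4"], y)


@pytest.fixture
def imbalanced_table(rng):
    """50 majority-0 vs 10 minority-1 rows, 3 features."""
    X = rng.standard_normal((60, 3))
    y = np.array([0] * 50 + [1] * 10)
    X[y == 1] += 2.0
    return FeatureTable(X, ["a", "b", "c"], y)


@pytest.fixture
def separable_table():
    """Strong-signal synthetic voice-style table, quick to classify."""
    spec = SyntheticSpec(
        n_samples=200, n_features=5, class1_fraction=0.5, mean_shift=3.0, seed=7
    )
    return generate_voice_like(spec)
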