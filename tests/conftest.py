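import numpy as np
import pytest

from ppdnet.network import TrainConfig
from ppdnet.schema import Dataset, default_schema
from ppdnet.synthetic import default_spec, generate


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def synth_default():
    """Full-size default synthetic cohort (1,503 records)."""
    return generate(default_spec(seed=0))


@pytest.fixture(scope="session")
def synth_small():
    """Small synthetic cohort for training-speed-sensitive tests."""
    return generate(default_spec(n=300, seed=1))


@pytest.fixture
def fast_cfg():
    """A cheap training config for protocol (not quality) tests."""
    return TrainConfig(epochs=5, hidden_sizes=(4,), batch_size=64, seed=0)


@pytest.fixture(scope="session")
def separable_toy(schema):
    """Linearly separable 20-record toy set: positives answer "yes"
    (code 1) to every symptom item, negatives answer "no" (code 3)."""
    pos = np.ones((10, 9), dtype=np.int64)
    neg = np.full((10, 9), 3, dtype=np.int64)
    neg[:, 0] = 1  # Age codes stay valid
    X = np.vstack([pos, neg])
    y = np.array([1] * 10 + [0] * 10)
    return Dataset(X, y, schema)


def make_dataset(X, y):
    return Dataset(np.asarray(X), np.asarray(y), default_schema())
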