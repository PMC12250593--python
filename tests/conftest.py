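import numpy as np
import pytest

from fedecg.data import normalize_features, split_dataset
from fedecg.gru import GRUConfig, TrainConfig
from fedecg.synthetic import generate_dataset

# Desk-scale experiment preset: reduced model and records short enough for
# numpy BPTT, while keeping the 4-class separable rhythm structure.
TEST_FS = 100.0
TEST_MODEL = GRUConfig(hidden_size=16, num_layers=2, fusion=True, pool=10)
TEST_TRAIN = TrainConfig(batch_size=16, learning_rate=0.005)


def make_normalized_split(n: int, seed: int, fs: float = TEST_FS):
    records = generate_dataset(n, seed=seed, fs=fs)
    split = split_dataset(records, seed=seed)
    split, _ = normalize_features(split)
    return split


@pytest.fixture(scope="session")
def split_cache():
    """Memoized clean separable datasets keyed by (n, seed)."""
    cache = {}

    def get(n: int, seed: int):
        key = (n, seed)
        if key not in cache:
            cache[key] = make_normalized_split(n, seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250928)
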