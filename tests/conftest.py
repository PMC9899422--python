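import numpy as np
import pytest

from speechmanifold import (
    ModelConfig,
    TrainingConfig,
    build_model,
    generate_dataset,
    standardize,
    train,
)


@pytest.fixture(scope="session")
def small_split():
    """4 classes x 10 train / 10 test exemplars at 32x16, standardized."""
    split = generate_dataset(4, 20, 0.5, seed=5, n_bands=32, n_frames=16)
    split, _ = standardize(split)
    return split


@pytest.fixture(scope="session")
def tiny_model(small_split):
    """A briefly-trained tinyconv on the small split (shared, read-only)."""
    model = build_model(ModelConfig("tinyconv", 4, (32, 16)), seed=3)
    train(model, small_split, TrainingConfig(epochs=3, seed=1, learning_rate=0.002))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
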