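import numpy as np
import pytest

import offgru as og
from offgru.encoding import encode_batch
from offgru.network import ModelConfig, ModelHandle, TrainConfig, train


@pytest.fixture(scope="session")
def fixture_pairs():
    return og.worked_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """600 mismatch-only pairs at IR 10 with the default planted rule."""
    cfg = og.SyntheticConfig(n_guides=6, pairs_per_guide=100, seed=11)
    pairs, truth = og.generate(cfg)
    return pairs, truth


@pytest.fixture(scope="session")
def indel_dataset():
    cfg = og.SyntheticConfig(n_guides=4, pairs_per_guide=50,
                             indel_fraction=0.2, seed=7)
    pairs, truth = og.generate(cfg)
    return pairs, truth


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A reduced architecture for tests that only exercise plumbing."""
    return ModelConfig(conv_kernel_widths=[1, 3], conv_filters=4,
                       bigru_units=[6, 4], dense_units=[16])


@pytest.fixture(scope="session")
def trained_tiny(small_dataset, tiny_model_cfg):
    """A briefly trained small model on the 600-pair dataset."""
    pairs, _ = small_dataset
    X = encode_batch(pairs, "7ch")
    y = np.array([p.label for p in pairs])
    model = ModelHandle(tiny_model_cfg, seed=3)
    train(model, X, y, TrainConfig(epochs=4, batch_size=128))
    return model, X, y
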