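import numpy as np
import pytest

import gpd
from gpd.design import TrainConfig, _featurize_dataset, train
from gpd.model import ModelConfig

TOY_SEED = 11
TRAIN_SEED = 3


@pytest.fixture(scope="session")
def helix():
    return gpd.helix_backbone(20)


@pytest.fixture(scope="session")
def toy_dataset():
    """5 helix/loop proteins of length 40 with a structure->sequence signal."""
    return gpd.make_toy_dataset(5, 40, seed=TOY_SEED)


@pytest.fixture(scope="session")
def trained_model(toy_dataset):
    """Small model overfit to the toy dataset (shared across tests).

    Returns (state, model config, featurized dataset, loss history).
    """
    cfg = ModelConfig.small()
    state, history = train(toy_dataset,
                           TrainConfig(epochs=300, batch_size=1,
                                       seed=TRAIN_SEED),
                           cfg)
    feats = _featurize_dataset(toy_dataset, cfg.d_noise)
    return state, cfg, feats, history


@pytest.fixture()
def rigid_transforms():
    """20 seeded random rotations + translations."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(123)
    out = []
    for _ in range(20):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(0, 25.0, size=3)
        out.append((R, t))
    return out
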