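import numpy as np
import pytest

from pdeseray import AugmentConfig, ModelConfig, SyntheticSpec, TrainConfig
from pdeseray.synthetic import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest valid architecture: 64 px input, one block per stage."""
    return ModelConfig(input_size=64, embed_dim=8, stage_depths=(1, 1, 1, 1),
                       stage_dims=(8, 16, 32, 64),
                       decoder_channels=(8, 8, 8, 8, 8))


@pytest.fixture
def tiny_train_config(tiny_model_config, tmp_path):
    return TrainConfig(model=tiny_model_config, batch_size=8, max_epochs=2,
                       seed=0, augment_train=False,
                       checkpoint_dir=str(tmp_path / "ckpt"),
                       augment=AugmentConfig(target_size=64))


@pytest.fixture
def synthetic_batch(tmp_path):
    """Eight 64-px synthetic radiographs written to disk with a manifest."""
    spec = SyntheticSpec(image_size=64, prevalence=0.5, seed=3)
    records = generate_dataset(spec, 8, tmp_path / "data")
    return records
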