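import numpy as np
import pytest

from bcpseg import LossConfig, ModelConfig, SynthConfig, TrainConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 32-px dataset shared by trainer-level tests."""
    cfg = SynthConfig(image_size=32, n_images=40, lesions_per_image=(1, 2),
                      lesion_radius_range=(3.0, 6.0), seed=7)
    return generate_dataset(cfg, label_ratio=0.25, val_fraction=0.2)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(first_encoder_channels=4, depth=3)


@pytest.fixture
def fast_train_cfg():
    return TrainConfig(pretrain_iterations=20, ssl_iterations=15,
                       batch_labeled=8, batch_unlabeled=8,
                       eval_every=10, seed=0)


@pytest.fixture
def loss_cfg():
    return LossConfig()
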