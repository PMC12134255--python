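import pytest

from nucleovit.evt import ClsTrainConfig, EVTConfig, train_classifier
from nucleovit.segmentation import ResUnetConfig, SegTrainConfig, train_segmentation
from nucleovit.synthetic import benign_spec, generate_sample, malignant_spec

from _utils import make_samples, to_cls_samples


@pytest.fixture(scope="session")
def small_evt_config():
    return EVTConfig(embed_dim=32, tokenizer_channels=(8, 16), encoder_layers=2,
                     attention_heads=2, dropout=0.0)


@pytest.fixture(scope="session")
def small_seg_config():
    return ResUnetConfig(depth=3, base_channels=8)


@pytest.fixture(scope="session")
def labeled_pair():
    return generate_sample(benign_spec(seed=3)), generate_sample(malignant_spec(seed=4))


# ---- heavier, lazily-built shared fixtures ---------------------------------

@pytest.fixture(scope="session")
def trained_seg(small_seg_config):
    """ResUnet trained on 20 synthetic samples for 50 epochs + 5 held-out."""
    train = make_samples(20, seed0=100)
    val = make_samples(5, seed0=900)
    model, history = train_segmentation(
        train, val, small_seg_config, SegTrainConfig(epochs=50, seed=42))
    return model, history, val


@pytest.fixture(scope="session")
def trained_evt(small_evt_config):
    """EVT trained to overfit 16 synthetic samples over 100 epochs."""
    samples = to_cls_samples(make_samples(16, seed0=200))
    model, history = train_classifier(
        samples, [], small_evt_config, ClsTrainConfig(epochs=100, seed=42))
    return model, history, samples


@pytest.fixture(scope="session")
def quick_evt(small_evt_config):
    """EVT trained briefly (visual-analysis fixtures)."""
    samples = to_cls_samples(make_samples(8, seed0=500))
    model, _ = train_classifier(
        samples, [], small_evt_config, ClsTrainConfig(epochs=15, warmup=3, seed=7))
    return model, samples
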