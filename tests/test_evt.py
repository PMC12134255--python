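import json
import math

import numpy as np
import pytest

from nucleovit import nn
from nucleovit.autograd import Tensor
from nucleovit.evt import (ClsTrainConfig, EVTConfig,
                           MultiheadAttention, SequencePool, TokenGrid,
                           build_evt, deterministic_inference, haar_dwt2,
                           load_checkpoint, save_checkpoint, train_classifier,
                           warmup_cosine_lr)
from _utils import make_samples, to_cls_samples


def tiny(**kw):
    base = dict(embed_dim=32, tokenizer_channels=(8, 16), encoder_layers=2,
                attention_heads=2, dropout=0.0)
    base.update(kw)
    return EVTConfig(**base)


# --------------------------------------------------------------- tokenizer

def test_tokenize_224_grid_28():
    model = build_evt(tiny(), seed=0)
    grid = model.tokenizer(Tensor(np.zeros((1, 3, 224, 224), np.float32)))
    assert (grid.grid_h, grid.grid_w) == (28, 28)
    assert grid.tokens.shape == (1, 784, 32)


def test_tokenize_64_sequence_length():
    model = build_evt(tiny(), seed=0)
    grid = model.tokenizer(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    assert grid.tokens.shape[1] == 64


def test_tokenize_zero_input_zero_biases_gives_zero_tokens():
    model = build_evt(tiny(), seed=1)
    for block in model.tokenizer.conv_layers:
        block[0].bias.data[:] = 0.0
    grid = model.tokenizer(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    assert np.abs(grid.tokens.data).max() == 0.0


def test_tokenize_rejects_non_32_divisible():
    model = build_evt(tiny(), seed=0)
    with pytest.raises(ValueError, match="32"):
        model.tokenizer(Tensor(np.zeros((1, 3, 60, 60), np.float32)))


def test_token_grid_roundtrip_lossless():
    tokens = Tensor(np.random.default_rng(0).standard_normal((1, 12, 5)))
    grid = TokenGrid(tokens=tokens, grid_h=3, grid_w=4)
    re = grid.tokens.data.reshape(1, 3, 4, 5).reshape(1, 12, 5)
    assert np.array_equal(re, tokens.data)
    with pytest.raises(ValueError):
        TokenGrid(tokens=tokens, grid_h=3, grid_w=5)


# --------------------------------------------------------------------- wpe

def test_wpe_preserves_shape():
    model = build_evt(tiny(), seed=2)
    grid = model.tokenizer(Tensor(np.random.default_rng(2)
                                  .standard_normal((2, 3, 64, 64)).astype(np.float32)))
    out = model.wpe(grid)
    assert out.tokens.shape == grid.tokens.shape


def test_wpe_zero_weights_is_identity():
    model = build_evt(tiny(), seed=3)
    model.wpe.zero_()
    grid = model.tokenizer(Tensor(np.random.default_rng(3)
                                  .standard_normal((1, 3, 64, 64)).astype(np.float32)))
    out = model.wpe(grid)
    assert np.array_equal(out.tokens.data, grid.tokens.data)


def test_wpe_zero_network_matches_no_wpe_network_exactly():
    cfg = tiny()
    m_wpe = build_evt(cfg, seed=3)
    m_wpe.wpe.zero_()
    m_plain = build_evt(tiny(wpe_enabled=False), seed=99)
    m_plain.load_state_dict(m_wpe.state_dict())
    x = Tensor(np.random.default_rng(5).standard_normal((2, 3, 64, 64)).astype(np.float32))
    assert np.array_equal(m_wpe.eval()(x).data, m_plain.eval()(x).data)


def test_haar_ll_constant_field():
    k = 3.25
    x = Tensor(np.full((1, 1, 4, 4), k))
    ll, lh, hl, hh = haar_dwt2(x)
    # oracle: 2x2 block sums halved
    assert np.allclose(ll.data, 2.0 * k)
    assert np.abs(lh.data).max() == 0.0
    assert np.abs(hl.data).max() == 0.0
    assert np.abs(hh.data).max() == 0.0


def test_haar_matches_block_oracle():
    rng = np.random.default_rng(7)
    arr = rng.standard_normal((1, 2, 6, 8))
    ll = haar_dwt2(Tensor(arr))[0].data
    for i in range(3):
        for j in range(4):
            block = arr[:, :, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
            assert np.allclose(ll[:, :, i, j], block.sum(axis=(2, 3)) / 2.0)


# ----------------------------------------------------------------- encoder

def test_encoder_shape_preserved_any_depth(small_evt_config):
    for layers in (1, 3):
        model = build_evt(tiny(encoder_layers=layers), seed=0)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 3, 64, 64)).astype(np.float32))
        assert model(x).shape == (1, 2)


def test_attention_rows_sum_to_one():
    rng = np.random.default_rng(11)
    att_logits = Tensor(rng.standard_normal((2, 2, 5, 5)))
    att = nn.softmax(att_logits, axis=-1)
    assert np.allclose(att.data.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_permutation_equivariance():
    rng = np.random.default_rng(13)
    mha = MultiheadAttention(8, 2, rng, dropout=0.0,
                             drop_rng=np.random.default_rng(0))
    mha.eval()
    x = rng.standard_normal((1, 4, 8)).astype(np.float32)
    perm = [2, 0, 3, 1]
    out = mha(Tensor(x)).data
    out_perm = mha(Tensor(x[:, perm])).data
    assert np.allclose(out[:, perm], out_perm, atol=1e-5)


def test_config_head_divisibility():
    with pytest.raises(ValueError):
        EVTConfig(embed_dim=30, attention_heads=4)


# ---------------------------------------------------------- sequence pool

def test_seq_pool_single_token_identity():
    rng = np.random.default_rng(17)
    pool = SequencePool(6, rng)
    tok = rng.standard_normal((1, 1, 6)).astype(np.float32)
    assert np.allclose(pool(Tensor(tok)).data, tok[0], atol=1e-6)


def test_seq_pool_identical_tokens():
    rng = np.random.default_rng(19)
    pool = SequencePool(6, rng)
    tok = np.tile(rng.standard_normal((1, 1, 6)).astype(np.float32), (1, 7, 1))
    assert np.allclose(pool(Tensor(tok)).data, tok[0, 0], atol=1e-6)


def test_seq_pool_two_token_closed_form():
    rng = np.random.default_rng(23)
    pool = SequencePool(2, rng)
    pool.proj.weight.data = np.array([[1.0], [0.0]], dtype=np.float32)
    pool.proj.bias.data = np.array([0.0], dtype=np.float32)
    tokens = np.array([[[1.0, 0.0], [3.0, 0.0]]], dtype=np.float32)
    w1 = math.exp(1.0) / (math.exp(1.0) + math.exp(3.0))
    w2 = math.exp(3.0) / (math.exp(1.0) + math.exp(3.0))
    expected = w1 * tokens[0, 0] + w2 * tokens[0, 1]
    assert np.allclose(pool(Tensor(tokens)).data[0], expected, atol=1e-6)


# -------------------------------------------------------------- classifier

def test_probabilities_sum_to_one():
    model = build_evt(tiny(), seed=0)
    x = Tensor(np.random.default_rng(1).standard_normal((3, 3, 64, 64)).astype(np.float32))
    p = model.predict_proba(x)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_zero_head_gives_uniform_probabilities():
    model = build_evt(tiny(), seed=0)
    model.classifier.weight.data[:] = 0.0
    model.classifier.bias.data[:] = 0.0
    x = Tensor(np.random.default_rng(2).standard_normal((2, 3, 64, 64)).astype(np.float32))
    assert np.allclose(model.predict_proba(x), 0.5)


def test_softmax_closed_form():
    logits = Tensor(np.array([[0.0, math.log(3.0)]]))
    p = nn.softmax(logits, axis=-1).data
    assert np.allclose(p, [[0.25, 0.75]], atol=1e-9)


# ---------------------------------------------------------------- training

def test_warmup_schedule_paper_table():
    cfg = ClsTrainConfig(epochs=100, warmup=5)
    assert warmup_cosine_lr(0, cfg) < warmup_cosine_lr(4, cfg)
    assert warmup_cosine_lr(4, cfg) < warmup_cosine_lr(5, cfg)
    assert warmup_cosine_lr(5, cfg) == pytest.approx(0.001)
    assert warmup_cosine_lr(99, cfg) < 1e-5


def test_missing_label_error_names_row():
    samples = [("row7", None, np.zeros((3, 64, 64), np.float32))]
    with pytest.raises(ValueError, match="row7"):
        train_classifier(samples, [], tiny(), ClsTrainConfig(epochs=2, warmup=1))


def test_epoch0_loss_deterministic():
    samples = to_cls_samples(make_samples(4, seed0=700))
    cfg = ClsTrainConfig(epochs=1, warmup=0, seed=11)
    _, h1 = train_classifier(samples, [], tiny(), cfg)
    _, h2 = train_classifier(samples, [], tiny(), cfg)
    assert h1[0]["loss"] == h2[0]["loss"]


def test_ablation_arms_constructible():
    arms = {
        "evt": tiny(wpe_enabled=False),
        "evt_wpe": tiny(wpe_enabled=True),
    }
    for cfg in arms.values():
        model = build_evt(cfg, seed=0)
        assert (model.wpe is not None) == cfg.wpe_enabled


# --------------------------------------------------------------- inference

@pytest.fixture(scope="module")
def quick_model():
    samples = to_cls_samples(make_samples(6, seed0=800))
    model, _ = train_classifier(samples, [], tiny(),
                                ClsTrainConfig(epochs=3, warmup=1, seed=5))
    return model, samples


def test_inference_repeatable(quick_model):
    model, samples = quick_model
    r1 = deterministic_inference(model, samples)
    r2 = deterministic_inference(model, samples)
    assert json.dumps(r1) == json.dumps(r2)


def test_inference_order_independent(quick_model):
    model, samples = quick_model
    base = {r["id"]: r for r in deterministic_inference(model, samples)}
    shuffled = [samples[i] for i in [3, 0, 5, 1, 4, 2]]
    for r in deterministic_inference(model, shuffled):
        assert json.dumps(r) == json.dumps(base[r["id"]])


def test_predictions_argmax_consistent(quick_model):
    model, samples = quick_model
    for r in deterministic_inference(model, samples):
        expected = "malignant" if r["p_malignant"] > 0.5 else "benign"
        if abs(r["p_malignant"] - 0.5) > 1e-9:
            assert r["pred_label"] == expected


def test_checkpoint_roundtrip(quick_model, tmp_path):
    model, samples = quick_model
    path = save_checkpoint(model, tmp_path / "evt.npz", seed=5)
    restored = load_checkpoint(path)
    r1 = deterministic_inference(model, samples)
    r2 = deterministic_inference(restored, samples)
    assert json.dumps(r1) == json.dumps(r2)
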