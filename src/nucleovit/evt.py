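"""Compact vision transformer with wavelet position embedding (WPE).

Stages: a three-block convolutional tokenizer (conv -> ReLU -> MaxPool),
an optional WPE that injects position information derived from a
single-level Haar decomposition of the token grid, a pre-norm transformer
encoder, attention-based sequence pooling, and a linear classifier head.

The WPE is a residual branch: (1) reshape tokens to their 2-D grid;
(2) Haar-decompose each channel and map the concatenated subbands through a
learned 1x1 projection into a per-position scale field, upsampled back to
grid size; (3) depthwise-convolve the grid; (4) gate the convolved grid with
sin and cos of the scale field; (5) add the result back onto the tokens.
Zero weights therefore make it an exact identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, cat, upsample2x_nearest
from .enhancement import normalize_for_classifier, resize_to_multiple

__all__ = [
    "EVTConfig", "ClsTrainConfig", "TokenGrid", "EVT", "build_evt",
    "haar_dwt2", "warmup_cosine_lr", "train_classifier",
    "deterministic_inference", "load_classification_samples",
    "save_checkpoint", "load_checkpoint", "LABEL_TO_INDEX", "INDEX_TO_LABEL",
]

LABEL_TO_INDEX = {"benign": 0, "malignant": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}


@dataclass(frozen=True)
class EVTConfig:
    embed_dim: int = 256
    tokenizer_channels: tuple[int, int] = (64, 128)
    conv_kernel: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2
    encoder_layers: int = 7
    attention_heads: int = 4
    mlp_ratio: int = 2
    n_classes: int = 2
    dropout: float = 0.1
    wpe_enabled: bool = True
    wavelet: str = "haar"

    def __post_init__(self):
        if self.embed_dim % self.attention_heads:
            raise ValueError("embed_dim must be divisible by attention_heads")
        if self.wavelet != "haar":
            raise ValueError("only the Haar wavelet is implemented")


@dataclass(frozen=True)
class ClsTrainConfig:
    epochs: int = 100
    warmup: int = 5
    batch_size: int = 2
    initial_lr: float = 0.001
    weight_decay: float = 1e-4
    seed: int = 42

    def __post_init__(self):
        if self.warmup >= self.epochs:
            raise ValueError("warmup must be < epochs")
        if min(self.epochs, self.batch_size) < 1 or self.initial_lr <= 0:
            raise ValueError("epochs, batch_size, initial_lr must be positive")


@dataclass
class TokenGrid:
    tokens: Tensor                  # (N, L, D)
    grid_h: int
    grid_w: int

    def __post_init__(self):
        if self.tokens.shape[1] != self.grid_h * self.grid_w:
            raise ValueError("sequence length must equal grid_h * grid_w")


class Tokenizer(nn.Module):
    """Three conv blocks (3x3 conv s1 p1 -> ReLU -> 3x3 MaxPool s2 p1)."""

    def __init__(self, config: EVTConfig, rng):
        super().__init__()
        c1, c2 = config.tokenizer_channels
        widths = [3, c1, c2, config.embed_dim]
        blocks = []
        for i in range(3):
            blocks.append(nn.ModuleList([
                nn.Conv2d(widths[i], widths[i + 1], config.conv_kernel, rng,
                          padding=config.conv_kernel // 2),
                nn.ReLU(),
                nn.MaxPool2d(config.pool_kernel, config.pool_stride,
                             padding=config.pool_kernel // 2),
            ]))
        self.conv_layers = nn.ModuleList(blocks)

    def forward(self, x: Tensor) -> TokenGrid:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"tokenizer input {x.shape[2]}x{x.shape[3]} must be 32-divisible")
        for block in self.conv_layers:
            for layer in block:
                x = layer(x)
        n, d, gh, gw = x.shape
        tokens = x.transpose(0, 2, 3, 1).reshape(n, gh * gw, d)  # row-major
        return TokenGrid(tokens=tokens, grid_h=gh, grid_w=gw)


def haar_dwt2(x: Tensor):
    """Single-level orthonormal 2-D Haar transform of (N, C, H, W), H, W even.

    Returns (LL, LH, HL, HH), each (N, C, H/2, W/2); a constant field k maps
    to LL = 2k.
    """
    a = x[:, :, ::2, ::2]
    b = x[:, :, ::2, 1::2]
    c = x[:, :, 1::2, ::2]
    d = x[:, :, 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return ll, lh, hl, hh


class WaveletPositionEmbedding(nn.Module):
    def __init__(self, embed_dim: int, rng, zero_init: bool = False):
        super().__init__()
        self.embed_dim = embed_dim
        self.subband_proj = nn.Conv2d(4 * embed_dim, embed_dim, 1, rng)
        self.depthwise = nn.Conv2d(embed_dim, embed_dim, 3, rng, padding=1,
                                   groups=embed_dim)
        if zero_init:
            self.zero_()

    def zero_(self):
        for p in self.parameters():
            p.data = np.zeros_like(p.data)

    def forward(self, grid: TokenGrid) -> TokenGrid:
        n, L, d = grid.tokens.shape
        gh, gw = grid.grid_h, grid.grid_w
        x = grid.tokens.transpose(0, 2, 1).reshape(n, d, gh, gw)
        xe, he, we = x, gh, gw
        if gh % 2 or gw % 2:                      # reflect-pad odd dims
            if gh % 2:
                xe = cat([xe, xe[:, :, -1:, :]], axis=2)
                he = gh + 1
            if gw % 2:
                xe = cat([xe, xe[:, :, :, -1:]], axis=3)
                we = gw + 1
        ll, lh, hl, hh = haar_dwt2(xe)
        scale = upsample2x_nearest(
            self.subband_proj(cat([ll, lh, hl, hh], axis=1)))
        conv = self.depthwise(xe)
        emb = conv * scale.sin() + conv * scale.cos()
        emb = emb[:, :, :gh, :gw]
        tokens = grid.tokens + emb.reshape(n, d, L).transpose(0, 2, 1)
        return TokenGrid(tokens=tokens, grid_h=gh, grid_w=gw)


class MultiheadAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng, dropout: float, drop_rng):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.drop = nn.Dropout(dropout, drop_rng)

    def forward(self, x: Tensor) -> Tensor:
        n, L, d = x.shape
        qkv = self.qkv(x).reshape(n, L, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)        # (3, N, h, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        att = nn.softmax(att, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, L, d)
        return self.drop(self.proj(out))


class EncoderBlock(nn.Module):
    """Pre-norm: x += MHA(LN(x)); x += MLP(LN(x))."""

    def __init__(self, dim, heads, mlp_ratio, rng, dropout, drop_rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiheadAttention(dim, heads, rng, dropout, drop_rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Sequential([
            nn.Linear(dim, mlp_ratio * dim, rng),
            nn.GELU(),
            nn.Linear(mlp_ratio * dim, dim, rng),
            nn.Dropout(dropout, drop_rng),
        ])

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class SequencePool(nn.Module):
    """Attention-weighted pooling of the token sequence into one vector."""

    def __init__(self, dim, rng):
        super().__init__()
        self.proj = nn.Linear(dim, 1, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        weights = nn.softmax(self.proj(tokens), axis=1)       # (N, L, 1)
        return (tokens * weights).sum(axis=1)                 # (N, D)


class EVT(nn.Module):
    def __init__(self, config: EVTConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        self.tokenizer = Tokenizer(config, rng)
        self.wpe = (WaveletPositionEmbedding(config.embed_dim, rng)
                    if config.wpe_enabled else None)
        self.encoder = nn.ModuleList([
            EncoderBlock(config.embed_dim, config.attention_heads,
                         config.mlp_ratio, rng, config.dropout, self.drop_rng)
            for _ in range(config.encoder_layers)])
        self.seq_pool = SequencePool(config.embed_dim, rng)
        self.classifier = nn.Linear(config.embed_dim, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        grid = self.tokenizer(x)
        if self.wpe is not None:
            grid = self.wpe(grid)
        tokens = grid.tokens
        for block in self.encoder:
            tokens = block(tokens)
        return self.classifier(self.seq_pool(tokens))

    def predict_proba(self, x: Tensor) -> np.ndarray:
        return nn.softmax(self.forward(x), axis=-1).data


def build_evt(config: EVTConfig | None = None, seed: int = 0) -> EVT:
    return EVT(config or EVTConfig(), seed=seed)


def warmup_cosine_lr(epoch: int, config: ClsTrainConfig) -> float:
    """Linear warmup to ``initial_lr`` at epoch ``warmup``, then cosine to 0."""
    if epoch < config.warmup:
        return config.initial_lr * (epoch + 1) / (config.warmup + 1)
    progress = (epoch - config.warmup) / max(1, config.epochs - config.warmup)
    return float(config.initial_lr * 0.5 * (1.0 + np.cos(np.pi * progress)))


def load_classification_samples(rows: list[dict], multiple: int = 32):
    """Manifest rows -> list of (id, label or None, normalized 3xHxW array)."""
    from .synthetic import load_image

    samples = []
    for row in rows:
        image = resize_to_multiple(load_image(row["image"]), multiple)
        label = row.get("label") or None
        if label is not None and label not in LABEL_TO_INDEX:
            raise ValueError(f"unknown label {label!r} for manifest row {row['id']!r}")
        samples.append((row["id"], label,
                        normalize_for_classifier(image).astype(np.float32)))
    return samples


def train_classifier(train_samples, val_samples, model_config: EVTConfig | None = None,
                     train_config: ClsTrainConfig | None = None,
                     model: EVT | None = None):
    """Train with Adam + warmup/cosine schedule; returns (best_model, history).

    ``train_samples`` / ``val_samples`` are (id, label, array) triples from
    :func:`load_classification_samples`.  The checkpoint with the best
    validation accuracy is retained (training accuracy when no validation
    set is given).
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("training set is empty")
    for sid, label, _ in train_samples:
        if label is None:
            raise ValueError(f"manifest row {sid!r} is missing a label")
    cfg = train_config or ClsTrainConfig()
    model = model or build_evt(model_config, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr,
                  weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history, best_acc, best_state = [], -1.0, model.state_dict()
    for epoch in range(cfg.epochs):
        opt.lr = warmup_cosine_lr(epoch, cfg)
        order = rng.permutation(len(train_samples))
        model.train()
        losses, n_correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[start:start + cfg.batch_size]]
            x = Tensor(np.stack([arr for _, _, arr in batch]))
            y = np.array([LABEL_TO_INDEX[label] for _, label, _ in batch])
            logits = model(x)
            loss = nn.cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            n_correct += int((logits.data.argmax(axis=1) == y).sum())
        train_acc = n_correct / len(train_samples)
        val_acc = (evaluate_accuracy(model, val_samples)
                   if val_samples else train_acc)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "train_acc": train_acc, "val_acc": val_acc,
                        "lr": opt.lr})
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def evaluate_accuracy(model: EVT, samples) -> float:
    preds = deterministic_inference(model, samples)
    pairs = [(p["pred_label"], p["true_label"]) for p in preds
             if p["true_label"] is not None]
    if not pairs:
        return float("nan")
    return float(np.mean([p == t for p, t in pairs]))


def deterministic_inference(model: EVT, samples) -> list[dict]:
    """Batch-1 sequential inference in sample order with all stochastic
    operations disabled; repeated calls are bit-identical."""
    model.eval()
    results = []
    for sid, label, arr in samples:
        proba = model.predict_proba(Tensor(arr[None]))[0]
        pred = int(proba.argmax())
        results.append({"id": sid, "true_label": label,
                        "pred_label": INDEX_TO_LABEL[pred],
                        "p_malignant": float(proba[LABEL_TO_INDEX["malignant"]])})
    return results


def write_predictions(preds: list[dict], path):
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["id", "true_label", "pred_label", "p_malignant"])
        writer.writeheader()
        writer.writerows(preds)
    return Path(path)


def save_checkpoint(model: EVT, path, seed: int | None = None):
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    cfg = asdict(model.config)
    meta = {"config": cfg, "seed": seed, "token_order": "row-major"}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return Path(path)


def load_checkpoint(path) -> EVT:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    cfg["tokenizer_channels"] = tuple(cfg["tokenizer_channels"])
    model = EVT(EVTConfig(**cfg))
    model.load_state_dict(state)
    return model
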