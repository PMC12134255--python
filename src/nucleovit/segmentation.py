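"""Residual U-Net nuclear segmenter with a hybrid BCE-Dice objective.

Architecture: 4-level (configurable) encoder/decoder with pre-activation
residual double-conv blocks, 2x max-pool downsampling, nearest-neighbour
upsampling + conv, and skip concatenation; a final 1x1 conv + sigmoid yields
a per-pixel foreground probability.  Training uses Adam with a step-decay
schedule (lr multiplied by ``lr_gamma`` every ``lr_step`` epochs) and
rotation / flip / intensity augmentation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, cat, upsample2x_nearest
from .metrics import dice as dice_score, jaccard as jaccard_score, mask_hausdorff
from .synthetic import LabeledImage

__all__ = [
    "ResUnetConfig", "SegTrainConfig", "ResUnet", "build_resunet",
    "bce_dice_loss", "soft_dice", "augment", "step_lr", "train_segmentation",
    "predict_mask", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ResUnetConfig:
    in_channels: int = 3
    out_channels: int = 1
    depth: int = 4
    base_channels: int = 32
    use_residual_blocks: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 100
    initial_lr: float = 1e-3
    lr_step: int = 30
    lr_gamma: float = 0.1
    seed: int = 42
    bce_weight: float = 1.0
    dice_weight: float = 1.0
    batch_size: int = 2
    augment: tuple[str, ...] = ("rotate", "flip", "intensity")

    def __post_init__(self):
        if not (0.0 < self.lr_gamma <= 1.0):
            raise ValueError("lr_gamma must lie in (0, 1]")
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.bce_weight == 0 and self.dice_weight == 0:
            raise ValueError("loss weights must not both be zero")


class _ResBlock(nn.Module):
    """Pre-activation residual double-conv block (identity 1x1 shortcut)."""

    def __init__(self, cin, cout, rng, residual=True):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1)
        self.residual = residual
        self.shortcut = (nn.Conv2d(cin, cout, 1, rng, bias=False)
                         if residual and cin != cout else None)

    def forward(self, x):
        h = self.conv2(self.conv1(x).relu()).relu()
        if not self.residual:
            return h
        s = self.shortcut(x) if self.shortcut is not None else x
        return h + s


class ResUnet(nn.Module):
    def __init__(self, config: ResUnetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2 ** i for i in range(config.depth)]
        self.encoders = nn.ModuleList(
            [_ResBlock(config.in_channels if i == 0 else ch[i - 1], ch[i], rng,
                       config.use_residual_blocks) for i in range(config.depth)])
        self.pool = nn.MaxPool2d(2, 2)
        self.bottleneck = _ResBlock(ch[-1], ch[-1] * 2, rng,
                                    config.use_residual_blocks)
        self.up_convs = nn.ModuleList(
            [nn.Conv2d(ch[i] * 2, ch[i], 3, rng, padding=1)
             for i in reversed(range(config.depth))])
        self.decoders = nn.ModuleList(
            [_ResBlock(ch[i] * 2, ch[i], rng, config.use_residual_blocks)
             for i in reversed(range(config.depth))])
        self.head = nn.Conv2d(ch[0], config.out_channels, 1, rng)

    def _check_dims(self, h, w):
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {div}; "
                f"resize first (see resize_to_multiple)")

    def forward(self, x: Tensor) -> Tensor:
        """x: (N,3,H,W) in [0,1] -> (N,1,H,W) probabilities."""
        self._check_dims(x.shape[2], x.shape[3])
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up_convs, self.decoders, reversed(skips)):
            x = up(upsample2x_nearest(x)).relu()
            x = dec(cat([skip, x], axis=1))
        return self.head(x).sigmoid()


def build_resunet(config: ResUnetConfig | None = None, seed: int = 0) -> ResUnet:
    return ResUnet(config or ResUnetConfig(), seed=seed)


def soft_dice(pred: Tensor, targ: Tensor, smooth: float = 1e-32) -> Tensor:
    inter = (pred * targ).sum()
    return (2.0 * inter + smooth) / (pred.sum() + targ.sum() + smooth)


def bce_dice_loss(pred, targ, bce_weight: float = 1.0,
                  dice_weight: float = 1.0, smooth: float = 1e-32) -> Tensor:
    """bce_weight * BCE + dice_weight * (1 - soft Dice); probabilities in, scalar out."""
    pred = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    targ = targ if isinstance(targ, Tensor) else Tensor(np.asarray(targ, dtype=np.float64))
    if pred.shape != targ.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {targ.shape}")
    if pred.data.min() < 0.0 or pred.data.max() > 1.0:
        raise ValueError("pred must be probabilities in [0, 1]")
    p = pred.clip(1e-7, 1.0 - 1e-7)
    bce = -(targ * p.log() + (1.0 - targ) * (1.0 - p).log()).mean()
    return bce * bce_weight + (1.0 - soft_dice(pred, targ, smooth)) * dice_weight


def augment(sample: LabeledImage, seed: int,
            ops: tuple[str, ...] = ("rotate", "flip", "intensity")) -> LabeledImage:
    """Seeded rotation/flip/intensity jitter; geometry applied to image and mask."""
    if sample.mask is None:
        raise ValueError("augment requires a mask")
    rng = np.random.default_rng(seed)
    img, mask = sample.image, sample.mask
    if "rotate" in ops:
        k = int(rng.integers(0, 4))
        img = np.rot90(img, k, axes=(0, 1))
        mask = np.rot90(mask, k, axes=(0, 1))
    if "flip" in ops:
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            img, mask = img[::-1], mask[::-1]
    if "intensity" in ops:
        factor = rng.uniform(0.9, 1.1)
        img = np.clip(np.rint(img.astype(np.float64) * factor), 0, 255).astype(np.uint8)
    return LabeledImage(image=np.ascontiguousarray(img),
                        mask=np.ascontiguousarray(mask),
                        label=sample.label, id=sample.id)


def step_lr(epoch: int, initial_lr: float, lr_step: int = 30,
            lr_gamma: float = 0.1) -> float:
    """initial_lr * lr_gamma ** floor(epoch / lr_step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial_lr * lr_gamma ** (epoch // lr_step)


def _to_input(image: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float (1,3,H,W) in [0,1]."""
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]


def predict_mask(model: ResUnet, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Threshold the probability map; returns a {0,1} uint8 mask."""
    prob = predict_probabilities(model, image)
    return (prob >= threshold).astype(np.uint8)


def predict_probabilities(model: ResUnet, image: np.ndarray) -> np.ndarray:
    model.eval()
    out = model(Tensor(_to_input(image)))
    return out.data[0, 0]


def _eval_model(model, samples):
    dices, jaccards, hausdorffs = [], [], []
    for s in samples:
        pred = predict_mask(model, s.image)
        dices.append(dice_score(pred, s.mask))
        jaccards.append(jaccard_score(pred, s.mask))
        try:
            hausdorffs.append(mask_hausdorff(pred, s.mask))
        except ValueError:
            pass                      # empty prediction or target: skip
    return (float(np.mean(dices)), float(np.mean(jaccards)),
            float(np.mean(hausdorffs)) if hausdorffs else float("nan"))


def train_segmentation(train_set, val_set, model_config: ResUnetConfig | None = None,
                       train_config: SegTrainConfig | None = None,
                       model: ResUnet | None = None):
    """Train a ResUnet; returns ``(best_model, history)``.

    ``history`` is a list of dicts with per-epoch loss, validation Dice /
    Jaccard / Hausdorff and the learning rate; the returned model carries the
    best-by-validation-Dice weights.  All randomness derives from
    ``train_config.seed``.
    """
    train_set, val_set = list(train_set), list(val_set)
    if not train_set:
        raise ValueError("training set is empty")
    cfg = train_config or SegTrainConfig()
    model = model or build_resunet(model_config, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed)
    history, best_dice, best_state = [], -1.0, model.state_dict()
    for epoch in range(cfg.epochs):
        opt.lr = step_lr(epoch, cfg.initial_lr, cfg.lr_step, cfg.lr_gamma)
        order = rng.permutation(len(train_set))
        model.train()
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            batch = [augment(train_set[i], int(rng.integers(0, 2 ** 31 - 1)),
                             cfg.augment) for i in batch_idx]
            x = Tensor(np.concatenate([_to_input(s.image) for s in batch]))
            y = Tensor(np.stack([s.mask for s in batch])[:, None].astype(np.float32))
            pred = model(x)
            loss = bce_dice_loss(pred, y, cfg.bce_weight, cfg.dice_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dice, val_jac, val_hd = (_eval_model(model, val_set)
                                     if val_set else (float("nan"),) * 3)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_dice": val_dice, "val_jaccard": val_jac,
                        "val_hausdorff": val_hd, "lr": opt.lr})
        if val_set and val_dice > best_dice:
            best_dice, best_state = val_dice, model.state_dict()
    if val_set:
        model.load_state_dict(best_state)
    return model, history


def write_history(history, path):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "loss", "val_dice", "val_jaccard",
                            "val_hausdorff", "lr"])
        writer.writeheader()
        writer.writerows(history)


def save_checkpoint(model: ResUnet, path, seed: int | None = None,
                    epoch: int | None = None):
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    meta = {"config": asdict(model.config), "seed": seed, "epoch": epoch}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return Path(path)


def load_checkpoint(path) -> ResUnet:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = dict(meta["config"])
    cfg_dict["depth"] = int(cfg_dict["depth"])
    model = ResUnet(ResUnetConfig(**cfg_dict))
    model.load_state_dict(state)
    return model
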