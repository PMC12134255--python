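"""Inspection tools: tokenizer feature-map colormaps and Grad-CAM.

Layers are addressed with dotted-index paths such as
``model.tokenizer.conv_layers[0][0]`` (first tokenizer convolution) or
``model.tokenizer.conv_layers[2][2]`` (last tokenizer max-pool).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from . import nn
from .autograd import Tensor
from .evt import EVT

__all__ = ["Heatmap", "resolve_layer", "available_layers",
           "tokenizer_activations", "featuremap_colormap", "grad_cam"]

logger = logging.getLogger(__name__)

_PATH_TOKEN = re.compile(r"\.?(\w+)|\[(\d+)\]")


def _parse_path(layer_path: str):
    pos, parts = 0, []
    for m in _PATH_TOKEN.finditer(layer_path):
        if m.start() != pos:
            raise ValueError(f"cannot parse layer path {layer_path!r}")
        pos = m.end()
        parts.append(m.group(1) if m.group(1) is not None else int(m.group(2)))
    if pos != len(layer_path):
        raise ValueError(f"cannot parse layer path {layer_path!r}")
    if parts and parts[0] == "model":
        parts = parts[1:]
    return parts


def available_layers(model: nn.Module, prefix: str = "model") -> list[str]:
    """All addressable conv / pooling layer paths in the model."""
    found = []

    def walk(mod, path):
        if isinstance(mod, (nn.Conv2d, nn.MaxPool2d)):
            found.append(path)
        if isinstance(mod, nn.ModuleList):
            for i, sub in enumerate(mod):
                walk(sub, f"{path}[{i}]")
        else:
            for name, sub in mod._modules.items():
                if isinstance(mod, nn.ModuleList) and name.isdigit():
                    continue
                walk(sub, f"{path}.{name}")

    walk(model, prefix)
    return found


def resolve_layer(model: nn.Module, layer_path: str):
    node = model
    for part in _parse_path(layer_path):
        try:
            node = node[part] if isinstance(part, int) else getattr(node, part)
        except (AttributeError, IndexError, TypeError):
            raise ValueError(
                f"layer path {layer_path!r} does not resolve; available: "
                + ", ".join(available_layers(model))) from None
    if not isinstance(node, (nn.Conv2d, nn.MaxPool2d)):
        raise ValueError(
            f"layer path {layer_path!r} is not a convolution or pooling layer; "
            "available: " + ", ".join(available_layers(model)))
    return node


def tokenizer_activations(model: EVT, normalized_image: np.ndarray) -> np.ndarray:
    """Activations before the tokenizer's flatten step, shape (C, H', W')."""
    layer = model.tokenizer.conv_layers[2][2]
    layer._capture = True
    try:
        model.eval()
        model.tokenizer(Tensor(normalized_image[None].astype(np.float32)))
    finally:
        layer._capture = False
    return layer.activation.data[0]


def featuremap_colormap(activations: np.ndarray, cmap: str = "viridis",
                        n_cols: int | None = None) -> np.ndarray:
    """Per-channel min-max normalize, x255, colormap; tiled uint8 RGB panel."""
    acts = np.asarray(activations, dtype=np.float64)
    n_ch, h, w = acts.shape
    mapper = colormaps[cmap]
    tiles = []
    for c in range(n_ch):
        ch = acts[c]
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            logger.warning("channel %d is constant (min = max); rendering mid-scale", c)
            scaled = np.full_like(ch, 127.0)
        else:
            scaled = (ch - lo) / (hi - lo) * 255.0
        rgba = mapper(scaled.astype(np.uint8))
        tiles.append((rgba[..., :3] * 255).astype(np.uint8))
    n_cols = n_cols or int(np.ceil(np.sqrt(n_ch)))
    n_rows = int(np.ceil(n_ch / n_cols))
    panel = np.zeros((n_rows * h, n_cols * w, 3), dtype=np.uint8)
    for c, tile in enumerate(tiles):
        r, k = divmod(c, n_cols)
        panel[r * h:(r + 1) * h, k * w:(k + 1) * w] = tile
    return panel


@dataclass
class Heatmap:
    values: np.ndarray                  # [0, 1] H x W
    layer_path: str
    overlay: np.ndarray | None = None   # uint8 RGB blend with source image


def grad_cam(model: EVT, layer_path: str, normalized_image: np.ndarray,
             target_class: int, source_image: np.ndarray | None = None,
             cmap: str = "jet") -> Heatmap:
    """Standard Grad-CAM at the addressed tokenizer layer.

    Channel weights are spatial means of the class-logit gradient; the
    weighted activation sum is rectified, upsampled to the input size, and
    max-normalized (all-zero maps stay all-zero).
    """
    layer = resolve_layer(model, layer_path)
    layer._capture = True
    try:
        model.eval()
        x = Tensor(normalized_image[None].astype(np.float32), requires_grad=True)
        logits = model(x)
        logits[0, int(target_class)].backward()
    finally:
        layer._capture = False
    act = layer.activation.data[0]                       # (C, h, w)
    grad = layer.activation.grad[0]
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    cam = _sk_resize(cam, normalized_image.shape[1:], order=1,
                     preserve_range=True, anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    heatmap = Heatmap(values=cam, layer_path=layer_path)
    if source_image is not None:
        rgba = colormaps[cmap](cam)
        colored = (rgba[..., :3] * 255).astype(np.float64)
        heatmap.overlay = np.clip(
            0.5 * source_image.astype(np.float64) + 0.5 * colored, 0, 255
        ).astype(np.uint8)
    return heatmap
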