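"""Deterministic H&E-like synthetic fixtures.

Images are a pink stroma background with darker elliptical nuclei; each
sample carries an exact binary nucleus mask and an optional class label.
Malignant presets draw larger, more eccentric, denser nuclei than benign
ones, mimicking the morphology shift the classifier is meant to pick up.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "SyntheticSpec", "LabeledImage", "NucleusPlacementError",
    "benign_spec", "malignant_spec", "generate_sample", "generate_dataset",
    "read_manifest",
]

BENIGN, MALIGNANT = "benign", "malignant"


class NucleusPlacementError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be placed."""


@dataclass(frozen=True)
class SyntheticSpec:
    width: int = 64
    height: int = 64
    n_nuclei: int = 8
    radius_range: tuple[float, float] = (4.0, 7.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.4)
    nucleus_color: tuple[int, int, int] = (64, 32, 128)
    stroma_color: tuple[int, int, int] = (230, 180, 200)
    noise_sd: float = 6.0
    blur_sigma: float = 0.8
    class_label: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("width and height must be >= 64")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range min must be <= max")
        if not (0.0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1.0):
            raise ValueError("eccentricity_range must lie in [0, 1)")


@dataclass
class LabeledImage:
    image: np.ndarray                       # uint8 H x W x 3
    mask: np.ndarray | None = None          # {0,1} H x W
    label: str | None = None
    id: str = ""

    def __post_init__(self):
        if self.mask is not None:
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError("mask shape must match image H x W")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask values must be 0/1")


def benign_spec(**overrides) -> SyntheticSpec:
    return replace(SyntheticSpec(
        n_nuclei=6, radius_range=(3.5, 5.0), eccentricity_range=(0.0, 0.3),
        class_label=BENIGN), **overrides)


def malignant_spec(**overrides) -> SyntheticSpec:
    return replace(SyntheticSpec(
        n_nuclei=7, radius_range=(5.5, 8.0), eccentricity_range=(0.5, 0.8),
        class_label=MALIGNANT), **overrides)


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = math.cos(theta), math.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_sample(spec: SyntheticSpec, max_retries: int = 1000) -> LabeledImage:
    """Draw ``spec.n_nuclei`` non-overlapping ellipses; fully seed-determined.

    Raises :class:`NucleusPlacementError` if a nucleus cannot be placed
    without overlap after ``max_retries`` rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.uint8)
    for k in range(spec.n_nuclei):
        placed = False
        for _ in range(max_retries):
            a = rng.uniform(*spec.radius_range)          # semi-major axis
            ecc = rng.uniform(*spec.eccentricity_range)
            b = a * math.sqrt(1.0 - ecc ** 2)            # semi-minor axis
            theta = rng.uniform(0.0, math.pi)
            cy = rng.uniform(a, h - a)
            cx = rng.uniform(a, w - a)
            ell = _ellipse_mask(h, w, cy, cx, a, b, theta)
            # 2 px separation margin keeps nuclei disconnected, not just disjoint
            grown = _ellipse_mask(h, w, cy, cx, a + 2.0, b + 2.0, theta)
            if not (mask & grown).any():
                mask[ell] = 1
                placed = True
                break
        if not placed:
            raise NucleusPlacementError(
                f"cannot place nuclei: nucleus {k + 1}/{spec.n_nuclei} failed "
                f"after {max_retries} retries")
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.stroma_color
    img[mask == 1] = spec.nucleus_color
    if spec.blur_sigma > 0:
        for c in range(3):
            img[:, :, c] = ndimage.gaussian_filter(img[:, :, c], spec.blur_sigma)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(image=img, mask=mask, label=spec.class_label,
                        id=f"{spec.class_label or 'sample'}_{spec.seed}")


def save_sample(sample: LabeledImage, image_path: Path, mask_path: Path | None = None):
    Image.fromarray(sample.image).save(image_path)
    if mask_path is not None and sample.mask is not None:
        Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mask_path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def generate_dataset(n_per_class: int, benign: SyntheticSpec,
                     malignant: SyntheticSpec, seed: int, out_dir) -> Path:
    """Write 2*n_per_class samples + masks and a CSV manifest; returns its path.

    Per-sample seeds are spawned deterministically from the master seed so a
    rerun with the same arguments reproduces every file byte for byte.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed_rng = np.random.default_rng(seed)
    rows = []
    for spec in (benign, malignant):
        for i in range(n_per_class):
            sample_seed = int(seed_rng.integers(0, 2 ** 31 - 1))
            sample = generate_sample(replace(spec, seed=sample_seed))
            sid = f"{spec.class_label}_{i:03d}"
            img_path = out_dir / f"{sid}.png"
            msk_path = out_dir / f"{sid}_mask.png"
            save_sample(sample, img_path, msk_path)
            rows.append((sid, img_path.name, msk_path.name, spec.class_label))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask", "label"])
        writer.writerows(rows)
    return manifest


def read_manifest(path) -> list[dict]:
    """Read a manifest CSV; relative file paths resolve against its directory."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            for key in ("image", "mask", "original"):
                if row.get(key):
                    p = Path(row[key])
                    if not p.is_absolute():
                        p = (path.parent / p).resolve()
                    row[key] = str(p)
            rows.append(row)
    return rows


def write_manifest(rows: list[dict], path, fieldnames=None):
    path = Path(path)
    if not rows and fieldnames is None:
        fieldnames = ["id", "image", "mask", "label"]
    fieldnames = fieldnames or list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return path
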