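"""Label-preserving, seeded augmentation: rotate, flip, crop, shift, scale.

Augmentation replaces each image with one transformed view per epoch (the
image count never changes and the label matrix is copied bitwise). Every
transform returns an image of the input shape:

* ``rotate(angle)`` — about the image center, bilinear, zero fill;
  positive angles are counterclockwise
* ``flip(axis)`` — mirror along ``"horizontal"`` (left/right) or
  ``"vertical"`` (up/down)
* ``crop(box)`` — extract ``(top, left, height, width)`` then resize back
* ``shift(dx, dy)`` — translate columns right by dx, rows down by dy,
  zero fill
* ``scale(factor)`` — resize about the center then center-crop (>1) or
  zero-pad (<1) back to the original shape

Per-image rng streams are keyed on ``(seed, epoch, image index)`` so
epoch-dynamic augmentation is reproducible regardless of loading order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage, as_array
from .prep import resize
from .synthpack import LabeledDataset

# ---------------------------------------------------------------------------
# transform descriptors


@dataclass(frozen=True)
class Rotate:
    angle_deg: float


@dataclass(frozen=True)
class Flip:
    axis: str  # "horizontal" | "vertical"


@dataclass(frozen=True)
class Crop:
    top: int
    left: int
    height: int
    width: int


@dataclass(frozen=True)
class Shift:
    dx: int
    dy: int


@dataclass(frozen=True)
class Scale:
    factor: float


Transform = Rotate | Flip | Crop | Shift | Scale


@dataclass
class AugmentPolicy:
    """Per-epoch sampling policy; defaults enable flips/rotations/crops."""

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    max_rotation_deg: float = 30.0
    crop_fraction_range: tuple[float, float] = (0.9, 1.0)
    max_shift_px: int = 0
    scale_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_flip_h, self.p_flip_v):
            if not (0.0 <= p <= 1.0):
                raise ValueError("flip probabilities must lie in [0, 1]")
        lo, hi = self.crop_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_fraction_range must be ordered within (0, 1]")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("scale_range must be ordered and positive")
        if self.max_rotation_deg < 0 or self.max_shift_px < 0:
            raise ValueError("max_rotation_deg and max_shift_px must be >= 0")


# ---------------------------------------------------------------------------
# single transforms


def apply_transform(img: GrayImage | np.ndarray, t: Transform) -> GrayImage:
    arr = as_array(img)
    tag = img.value_range if isinstance(img, GrayImage) else "unit"
    h, w = arr.shape
    if isinstance(t, Rotate):
        if t.angle_deg == 0.0:
            out = arr.copy()
        else:
            out = ndimage.rotate(arr, t.angle_deg, reshape=False, order=1, mode="constant", cval=0.0)
    elif isinstance(t, Flip):
        if t.axis == "horizontal":
            out = arr[:, ::-1].copy()
        elif t.axis == "vertical":
            out = arr[::-1, :].copy()
        else:
            raise ValueError(f"unknown flip axis {t.axis!r}")
    elif isinstance(t, Crop):
        if t.top < 0 or t.left < 0 or t.top + t.height > h or t.left + t.width > w or t.height < 1 or t.width < 1:
            raise ValueError(f"crop box {t} outside {arr.shape} image")
        out = resize(arr[t.top : t.top + t.height, t.left : t.left + t.width], h, w).values
    elif isinstance(t, Shift):
        out = np.zeros_like(arr)
        src_r = slice(max(0, -t.dy), max(0, min(h, h - t.dy)))
        dst_r = slice(max(0, t.dy), max(0, min(h, h + t.dy)))
        src_c = slice(max(0, -t.dx), max(0, min(w, w - t.dx)))
        dst_c = slice(max(0, t.dx), max(0, min(w, w + t.dx)))
        out[dst_r, dst_c] = arr[src_r, src_c]
    elif isinstance(t, Scale):
        if t.factor <= 0:
            raise ValueError("scale factor must be positive")
        if t.factor == 1.0:
            out = arr.copy()
        else:
            nh = max(1, round(h * t.factor))
            nw = max(1, round(w * t.factor))
            big = resize(arr, nh, nw).values
            out = np.zeros_like(arr)
            if nh >= h:  # center-crop back down
                top, left = (nh - h) // 2, (nw - w) // 2
                out = big[top : top + h, left : left + w].copy()
            else:  # center-pad back up with zeros
                top, left = (h - nh) // 2, (w - nw) // 2
                out[top : top + nh, left : left + nw] = big
    else:
        raise TypeError(f"unknown transform descriptor {t!r}")
    return GrayImage(out, tag)


# ---------------------------------------------------------------------------
# per-epoch augmentation


def sample_transforms(policy: AugmentPolicy, shape: tuple[int, int], rng: np.random.Generator) -> list[Transform]:
    """Draw one epoch's transform chain for a single image."""
    h, w = shape
    chain: list[Transform] = []
    if rng.random() < policy.p_flip_h:
        chain.append(Flip("horizontal"))
    if rng.random() < policy.p_flip_v:
        chain.append(Flip("vertical"))
    if policy.max_rotation_deg > 0:
        chain.append(Rotate(float(rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg))))
    lo, hi = policy.crop_fraction_range
    if hi < 1.0 or lo < 1.0:
        frac = float(rng.uniform(lo, hi))
        ch, cw = max(1, round(h * frac)), max(1, round(w * frac))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        chain.append(Crop(top, left, ch, cw))
    if policy.max_shift_px > 0:
        chain.append(
            Shift(
                int(rng.integers(-policy.max_shift_px, policy.max_shift_px + 1)),
                int(rng.integers(-policy.max_shift_px, policy.max_shift_px + 1)),
            )
        )
    lo, hi = policy.scale_range
    if (lo, hi) != (1.0, 1.0):
        chain.append(Scale(float(rng.uniform(lo, hi))))
    return chain


def augment_epoch(ds: LabeledDataset, policy: AugmentPolicy, epoch: int) -> LabeledDataset:
    """Replace each image with a freshly sampled view; labels untouched."""
    images = []
    for i, im in enumerate(ds.images):
        rng = np.random.default_rng([policy.seed, epoch, i])
        out = im
        for t in sample_transforms(policy, (im.height, im.width), rng):
            out = apply_transform(out, t)
        images.append(out if out is not im else im.copy())
    return LabeledDataset(images, ds.labels.copy(), [dict(r) for r in ds.records], ds.class_names)
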