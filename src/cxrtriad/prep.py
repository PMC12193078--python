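"""Preprocessing: Gaussian smoothing, resizing, intensity normalization.

Two dialects are provided because the pipeline is described with two
slightly different front ends and we do not guess which produced the
reported results:

* ``zscore-224`` — Gaussian filter → bilinear resize to ``target_size`` →
  per-image z-score (zero mean, unit population SD).
* ``imagenet-crop`` — Gaussian filter → resize to ``crop_source_size``
  (default 256) → seeded random crop to ``target_size`` (default 224) →
  fixed-statistics normalization ``(x − norm_mean) / norm_sd``.

The Gaussian kernel is the truncated sampled Gaussian
``exp(−(u² + v²) / (2 Z²))`` on a ``(2·radius+1)²`` support, renormalized
to sum 1 (the analytic ``1/(2πZ²)`` factor is absorbed by the
renormalization, so constants are preserved exactly). Borders use reflect
padding. Resizing is bilinear with the half-pixel-center convention, so
output values are convex combinations of input values and never leave the
input min/max range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage, as_array

# Grayscale ImageNet statistics: channel means/SDs collapsed to one channel.
IMAGENET_GRAY_MEAN = 0.449
IMAGENET_GRAY_SD = 0.226

DIALECTS = ("zscore-224", "imagenet-crop")


@dataclass
class PrepConfig:
    smoothing_Z: float = 1.0
    kernel_radius: int | None = None  # None -> ceil(3 Z)
    target_size: int = 224
    dialect: str = "zscore-224"
    crop_source_size: int = 256
    norm_mean: float = IMAGENET_GRAY_MEAN
    norm_sd: float = IMAGENET_GRAY_SD

    def __post_init__(self) -> None:
        if self.smoothing_Z <= 0:
            raise ValueError("smoothing_Z must be > 0")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")
        if self.dialect == "imagenet-crop" and self.target_size > self.crop_source_size:
            raise ValueError("target_size must not exceed crop_source_size for imagenet-crop")

    @property
    def radius(self) -> int:
        return self.kernel_radius if self.kernel_radius is not None else max(1, math.ceil(3 * self.smoothing_Z))


def gaussian_kernel(Z: float, radius: int) -> np.ndarray:
    """Renormalized truncated Gaussian kernel on a (2r+1)² support."""
    if Z <= 0:
        raise ValueError("smoothing factor Z must be > 0")
    if radius < 1:
        raise ValueError("kernel radius must be >= 1")
    u = np.arange(-radius, radius + 1, dtype=np.float64)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    k = np.exp(-(uu**2 + vv**2) / (2.0 * Z**2))
    return k / k.sum()


def gaussian_filter(img: GrayImage | np.ndarray, Z: float, radius: int | None = None) -> GrayImage:
    """Smooth with the normalized truncated Gaussian, reflect padding."""
    arr = as_array(img)
    if radius is None:
        radius = max(1, math.ceil(3 * Z))
    out = ndimage.convolve(arr, gaussian_kernel(Z, radius), mode="reflect")
    tag = img.value_range if isinstance(img, GrayImage) else "unit"
    return GrayImage(out, tag)


def resize(img: GrayImage | np.ndarray, h: int, w: int) -> GrayImage:
    """Bilinear resize with half-pixel centers; exact identity at same shape."""
    arr = as_array(img)
    if h < 1 or w < 1:
        raise ValueError("target shape must be >= 1 in both dimensions")
    hin, win = arr.shape
    if (h, w) == (hin, win):
        out = arr.copy()
    else:
        # destination pixel center (i+0.5) maps to source coordinate
        # (i+0.5)*scale - 0.5, clamped to the valid sample range
        ys = np.clip((np.arange(h) + 0.5) * (hin / h) - 0.5, 0, hin - 1)
        xs = np.clip((np.arange(w) + 0.5) * (win / w) - 0.5, 0, win - 1)
        y0 = np.floor(ys).astype(int)
        x0 = np.floor(xs).astype(int)
        y1 = np.minimum(y0 + 1, hin - 1)
        x1 = np.minimum(x0 + 1, win - 1)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        out = (
            arr[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
            + arr[np.ix_(y0, x1)] * (1 - fy) * fx
            + arr[np.ix_(y1, x0)] * fy * (1 - fx)
            + arr[np.ix_(y1, x1)] * fy * fx
        )
    tag = img.value_range if isinstance(img, GrayImage) else "unit"
    return GrayImage(out, tag)


def zscore_normalize(img: GrayImage | np.ndarray) -> GrayImage:
    """Per-image standardization (value − mean) / population SD.

    A constant image has no scale to divide by and maps to all zeros.
    """
    arr = as_array(img)
    if arr.size < 2:
        raise ValueError("z-score normalization needs at least 2 pixels")
    sd = arr.std()
    if sd == 0.0:
        return GrayImage(np.zeros_like(arr), "standardized")
    return GrayImage((arr - arr.mean()) / sd, "standardized")


def random_crop(img: GrayImage | np.ndarray, size: int, rng: np.random.Generator) -> GrayImage:
    arr = as_array(img)
    hin, win = arr.shape
    if size > hin or size > win:
        raise ValueError("crop size exceeds image")
    top = int(rng.integers(0, hin - size + 1))
    left = int(rng.integers(0, win - size + 1))
    tag = img.value_range if isinstance(img, GrayImage) else "unit"
    return GrayImage(arr[top : top + size, left : left + size].copy(), tag)


def preprocess(
    img: GrayImage | np.ndarray,
    cfg: PrepConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> GrayImage:
    """Run the configured dialect; deterministic given the rng seed."""
    cfg = cfg or PrepConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    smoothed = gaussian_filter(img, cfg.smoothing_Z, cfg.radius)
    if cfg.dialect == "zscore-224":
        return zscore_normalize(resize(smoothed, cfg.target_size, cfg.target_size))
    # imagenet-crop
    resized = resize(smoothed, cfg.crop_source_size, cfg.crop_source_size)
    cropped = random_crop(resized, cfg.target_size, rng)
    return GrayImage((cropped.values - cfg.norm_mean) / cfg.norm_sd, "standardized")
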