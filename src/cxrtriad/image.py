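"""Grayscale image container shared across the pipeline.

Images are 2-D float64 grids in row-major order with 0-based (row, col)
coordinates. A ``value_range`` tag records which convention the values
currently follow so stages can assert their preconditions:

* ``raw-8bit`` — integers in [0, 255] as read from PNG
* ``unit`` — reals in [0, 1]
* ``standardized`` — z-scored or fixed-statistics normalized reals
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALUE_RANGES = ("raw-8bit", "unit", "standardized")


@dataclass
class GrayImage:
    """A single-channel image with a declared value-range convention."""

    values: np.ndarray
    value_range: str = "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GrayImage values must be finite")
        if self.value_range not in VALUE_RANGES:
            raise ValueError(f"unknown value_range {self.value_range!r}; expected one of {VALUE_RANGES}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, value_range: str | None = None) -> "GrayImage":
        """Return a new image carrying ``values`` (same range tag by default)."""
        return GrayImage(values, self.value_range if value_range is None else value_range)

    def copy(self) -> "GrayImage":
        return GrayImage(self.values.copy(), self.value_range)


def as_array(img: "GrayImage | np.ndarray") -> np.ndarray:
    """Accept either a GrayImage or a bare 2-D array and return the array."""
    if isinstance(img, GrayImage):
        return img.values
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {arr.shape}")
    return arr
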