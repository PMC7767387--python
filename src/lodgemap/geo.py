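"""Minimal grid georeferencing and multi-band raster containers.

Rasters are row-major numpy grids with a north-up affine geotransform and a
pixel-centre coordinate convention: pixel (row, col) has its centre at
``(x0 + (col + 0.5) * pixel_size, y0 - (row + 0.5) * pixel_size)`` in a local
metric CRS whose origin is the upper-left corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform in a local metric CRS."""

    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 10.0

    def pixel_center(self, row, col):
        """Map (row, col) indices to (x, y) centre coordinates."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.pixel_size
        y = self.y0 - (row + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y):
        """Map world coordinates to fractional (row, col) indices."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.x0) / self.pixel_size - 0.5
        row = (self.y0 - y) / self.pixel_size - 0.5
        return row, col

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "pixel_size": self.pixel_size}

    @classmethod
    def from_dict(cls, d: dict) -> "GridTransform":
        return cls(x0=d["x0"], y0=d["y0"], pixel_size=d["pixel_size"])


@dataclass
class RasterStack:
    """Ordered stack of named, co-registered 2-D bands.

    Used both for optical reflectance stacks (bands B2..B12) and for derived
    SAR feature stacks (VV, VH, ... Span).  All bands share shape and
    geotransform.
    """

    bands: dict[str, np.ndarray]
    transform: GridTransform = field(default_factory=GridTransform)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands have mismatched shapes: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.bands[name]

    def select(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"bands not in stack: {missing}")
        return RasterStack({n: self.bands[n] for n in names}, self.transform, dict(self.meta))

    def merge(self, other: "RasterStack") -> "RasterStack":
        if other.shape != self.shape:
            raise ValueError("cannot merge stacks with different shapes")
        bands = dict(self.bands)
        bands.update(other.bands)
        return RasterStack(bands, self.transform, {**self.meta, **other.meta})

    def pixel_matrix(self, rows, cols, names: list[str] | None = None) -> np.ndarray:
        """Extract an (n_pixels, n_bands) feature matrix at integer indices."""
        names = names or self.names
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        return np.column_stack([self.bands[n][rows, cols] for n in names])

    def to_array(self, dtype=np.float32) -> np.ndarray:
        return np.stack([self.bands[n] for n in self.names]).astype(dtype)
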