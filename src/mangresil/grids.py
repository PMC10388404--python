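"""Raster containers.

Two in-memory raster types are used throughout the package:

* :class:`Grid` — a numeric raster (single band or a band stack) with a
  pixel size in metres and NaN as the nodata sentinel;
* :class:`ClassMap` — a categorical raster whose integer codes are tied to
  a legend (code -> class name), with ``-1`` as the nodata code.

Grids use a top-left origin, 0-based row/column indexing and half-open
extents; ``origin`` is the (x, y) of the top-left corner in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA_CODE = -1


@dataclass
class Grid:
    """Numeric raster: ``values`` is (rows, cols) or (bands, rows, cols)."""

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"Grid values must be 2-D or 3-D, got ndim={self.values.ndim}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols) regardless of band count."""
        return self.values.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    def band(self, i: int) -> "Grid":
        if self.values.ndim == 2:
            if i != 0:
                raise IndexError("single-band grid has only band 0")
            return self
        return replace(self, values=self.values[i])

    def same_geometry(self, other: "Grid | ClassMap") -> bool:
        return self.shape == other.shape and np.isclose(self.pixel_size, other.pixel_size)

    # -- data -----------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels valid in every band."""
        finite = np.isfinite(self.values)
        return finite if self.values.ndim == 2 else finite.all(axis=0)

    def with_values(self, values: np.ndarray) -> "Grid":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0


@dataclass
class ClassMap:
    """Categorical raster with legend; nodata pixels carry code ``-1``."""

    codes: np.ndarray
    legend: dict[int, str]
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise ValueError("ClassMap codes must be a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        present = set(np.unique(self.codes).tolist()) - {NODATA_CODE}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"codes not in legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def valid_mask(self) -> np.ndarray:
        return self.codes != NODATA_CODE

    def same_geometry(self, other: "Grid | ClassMap") -> bool:
        return self.shape == other.shape and np.isclose(self.pixel_size, other.pixel_size)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / 10_000.0


def require_aligned(a: Grid | ClassMap, b: Grid | ClassMap, what: str = "grids") -> None:
    if not a.same_geometry(b):
        raise ValueError(
            f"misaligned {what}: shapes {a.shape} vs {b.shape}, "
            f"pixel sizes {a.pixel_size} vs {b.pixel_size}"
        )


def as_binary_mask(mask: "Grid | np.ndarray") -> np.ndarray:
    """Validate and return a boolean mask from a 0/1 grid or array."""
    values = mask.values if isinstance(mask, Grid) else np.asarray(mask)
    finite = values[np.isfinite(values)] if values.dtype.kind == "f" else values
    if not np.isin(finite, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    out = np.zeros(values.shape, dtype=bool)
    out[np.where(values == 1)] = True
    return out
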