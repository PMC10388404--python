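"""Canopy height and aboveground-biomass rasters from a DEM.

Over a closed mangrove canopy a radar-interferometric DEM (e.g. SRTM)
records a height between the ground and the canopy top, close to the
basal-area-weighted (Lorey's) height.  Two empirical linear factors map it
to stand-height scales:

* maximum canopy height  H_max = 1.697 x H_DEM
* basal-area-weighted height  H_ba = 1.08 x H_DEM

and a power-law allometry converts H_ba to aboveground biomass density:

    B [Mg/ha] = 3.25 x H_ba ** 1.53

All operations are restricted to a mangrove-extent mask; pixels outside
the mask are nodata.  H_ba is computed from the original DEM, not from
H_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Grid, as_binary_mask, require_aligned


@dataclass
class HeightModelParams:
    hmax_factor: float = 1.697
    hba_factor: float = 1.08
    agb_scale: float = 3.25  # Mg/ha at unit H_ba
    agb_exponent: float = 1.53
    height_floor: float = 0.0  # heights below this clamp to 0 before the power law

    def __post_init__(self) -> None:
        for name in ("hmax_factor", "hba_factor", "agb_scale", "agb_exponent"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _masked(dem: Grid, mask: Grid | np.ndarray, factor: float) -> Grid:
    if isinstance(mask, Grid):
        require_aligned(dem, mask, "DEM and mask")
    keep = as_binary_mask(mask)
    if keep.shape != dem.shape:
        raise ValueError(f"mask shape {keep.shape} does not match DEM {dem.shape}")
    out = np.where(keep, factor * dem.values, np.nan)
    return dem.with_values(out)


def canopy_height_max(
    dem: Grid, mask: Grid | np.ndarray, p: HeightModelParams | None = None
) -> Grid:
    """Maximum canopy height (m): hmax_factor x DEM inside the mask."""
    p = p or HeightModelParams()
    return _masked(dem, mask, p.hmax_factor)


def basal_area_weighted_height(
    dem: Grid, mask: Grid | np.ndarray, p: HeightModelParams | None = None
) -> Grid:
    """Basal-area-weighted (Lorey's) height (m): hba_factor x DEM inside the mask."""
    p = p or HeightModelParams()
    return _masked(dem, mask, p.hba_factor)


def agb_from_height(hba: Grid, p: HeightModelParams | None = None) -> Grid:
    """Aboveground biomass density (Mg/ha) from H_ba via the power law."""
    p = p or HeightModelParams()
    values = hba.values
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("negative canopy heights; clamp or clean the input first")
    h = np.where(values < p.height_floor, 0.0, values)
    out = p.agb_scale * np.power(h, p.agb_exponent)
    return hba.with_values(out)


def zonal_summary(g: Grid, mask: Grid | np.ndarray) -> dict[str, float]:
    """min/max/mean/total and pixel count over valid masked pixels.

    ``total_per_area_units`` integrates a per-hectare density raster over
    the masked area (value x pixel area in ha), so for an AGB raster it is
    total biomass in Mg.
    """
    if isinstance(mask, Grid):
        require_aligned(g, mask, "grid and mask")
    keep = as_binary_mask(mask)
    values = g.values[keep]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty mask: no valid pixels to summarise")
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "total": float(values.sum()),
        "total_per_area_units": float(values.sum() * g.pixel_area_ha),
        "n_pixels": int(values.size),
        "area_ha": float(values.size * g.pixel_area_ha),
    }
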