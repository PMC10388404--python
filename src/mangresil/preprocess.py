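"""SAR calibration, NDVI compositing, speckle filtering and masking.

These are the standard preparation steps that run before land-cover
classification: raw SAR digital numbers (DN) are calibrated to backscatter
in decibels, optical bands are condensed into NDVI, SAR speckle is reduced
with a focal median, and cloud/extent masks are applied as generic binary
masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, as_binary_mask, require_aligned

#: Default PALSAR calibration factor in dB.  The sensor handbook value has
#: magnitude 83; the sign convention here yields physically plausible
#: (negative) backscatter over natural surfaces.
DEFAULT_CF_DB = -83.0


@dataclass
class CalibrationParams:
    """SAR radiometric calibration: ``cf`` is the additive factor in dB."""

    cf: float = DEFAULT_CF_DB

    def __post_init__(self) -> None:
        if not np.isfinite(self.cf):
            raise ValueError("calibration factor must be finite")


def dn_to_gamma0(dn: Grid, params: CalibrationParams | None = None) -> Grid:
    """Calibrate SAR digital numbers to gamma-naught backscatter in dB.

    gamma0 = 10 * log10(DN^2) + CF.  DN of zero has no defined backscatter
    and becomes nodata; negative DN is a data error.
    """
    params = params or CalibrationParams()
    values = dn.values
    n_negative = int(np.sum(values[np.isfinite(values)] < 0))
    if n_negative:
        raise ValueError(f"{n_negative} pixels have negative DN; DN must be >= 0")
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(values**2) + params.cf
    out = np.where(values == 0, np.nan, out)
    return dn.with_values(out)


def ndvi(nir: Grid, red: Grid) -> Grid:
    """Normalized difference vegetation index, (NIR - Red) / (NIR + Red).

    Pixels where NIR + Red == 0 become nodata.
    """
    require_aligned(nir, red, "NDVI bands")
    total = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (nir.values - red.values) / total
    out = np.where(total == 0, np.nan, out)
    return nir.with_values(out)


def speckle_filter(g: Grid, window: int = 3) -> Grid:
    """Focal-median speckle filter with an odd square window.

    Nodata-aware: a nodata pixel stays nodata; elsewhere the median is
    taken over the valid neighbours within the window (edges use the
    shrunken neighbourhood).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if g.values.ndim != 2:
        raise ValueError("speckle_filter expects a single-band grid")
    values = g.values
    if np.isfinite(values).all():
        out = ndimage.median_filter(values, size=window, mode="nearest")
    else:
        out = ndimage.generic_filter(
            values, np.nanmedian, size=window, mode="constant", cval=np.nan
        )
        out[~np.isfinite(values)] = np.nan
    return g.with_values(out)


def apply_mask(g: Grid, mask: Grid | np.ndarray) -> Grid:
    """Keep values where mask == 1; set nodata elsewhere."""
    if isinstance(mask, Grid):
        require_aligned(g, mask, "grid and mask")
    keep = as_binary_mask(mask)
    if keep.shape != g.shape:
        raise ValueError(f"mask shape {keep.shape} does not match grid {g.shape}")
    out = np.where(keep, g.values, np.nan)
    return g.with_values(out)
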