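"""Two-epoch land-use/land-cover accounting.

Class areas in hectares, signed percent change between epochs, and the
pixel-level class-transition cross-tabulation.  Nodata pixels are excluded
from all totals; a pixel that is nodata in either epoch is excluded from
the transition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import NODATA_CODE, ClassMap, require_aligned


@dataclass
class AreaTable:
    """Per-class areas (ha) for one epoch."""

    epoch: str
    areas_ha: dict[int, float]
    legend: dict[int, str]
    pixel_size: float

    @property
    def total_ha(self) -> float:
        return float(sum(self.areas_ha.values()))

    def to_series(self) -> pd.Series:
        return pd.Series(
            {self.legend[c]: self.areas_ha[c] for c in sorted(self.legend)}, name=self.epoch
        )


def class_areas(cm: ClassMap, epoch: str = "") -> AreaTable:
    """Area of each legend class: pixel count x pixel_size^2 / 10^4 ha."""
    pixel_ha = cm.pixel_area_ha
    areas = {
        code: float(np.count_nonzero(cm.codes == code)) * pixel_ha for code in sorted(cm.legend)
    }
    return AreaTable(epoch=epoch, areas_ha=areas, legend=dict(cm.legend), pixel_size=cm.pixel_size)


def percent_change(a1: AreaTable, a2: AreaTable) -> dict[int, float]:
    """Signed percent change per class, 100 * (a2 - a1) / a1.

    A class absent at the first epoch has undefined change (NaN).
    """
    if set(a1.legend) != set(a2.legend):
        raise ValueError("area tables have different legends")
    out: dict[int, float] = {}
    for code in sorted(a1.legend):
        before, after = a1.areas_ha[code], a2.areas_ha[code]
        out[code] = 100.0 * (after - before) / before if before > 0 else float("nan")
    return out


def transition_table(t1: ClassMap, t2: ClassMap) -> pd.DataFrame:
    """k x k hectare cross-tabulation of epoch-1 -> epoch-2 classes.

    Row sums reproduce epoch-1 class areas and column sums epoch-2 areas
    (over pixels valid in both epochs).
    """
    require_aligned(t1, t2, "epoch class maps")
    if set(t1.legend) != set(t2.legend):
        raise ValueError("epoch class maps have different legends")
    codes = sorted(t1.legend)
    valid = (t1.codes != NODATA_CODE) & (t2.codes != NODATA_CODE)
    k = len(codes)
    counts = np.zeros((k, k), dtype=np.int64)
    if valid.any():
        code_array = np.asarray(codes)
        i1 = np.searchsorted(code_array, t1.codes[valid])
        i2 = np.searchsorted(code_array, t2.codes[valid])
        np.add.at(counts, (i1, i2), 1)
    names = [t1.legend[c] for c in codes]
    return pd.DataFrame(counts * t1.pixel_area_ha, index=names, columns=names)
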