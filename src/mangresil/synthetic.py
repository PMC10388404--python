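"""Synthetic coastal-wetland scene generator.

Every input the assessment pipeline consumes can be generated here with
controlled statistical structure and a fixed seed: two-epoch four-class
land-cover rasters with a prescribed transition structure, per-class band
signatures (a SAR digital-number layer plus optical reflectance bands), a
DEM whose values inside the mangrove extent play the role of
canopy-height measurements, stratified labelled sample points, a
four-plot tree inventory on a 100-m transect, and shoreline points every
250 m carrying six hazard variables.

Epoch-1 classes are obtained by thresholding a smoothed Gaussian noise
field at the cumulative class fractions, so classes form spatially
coherent patches rather than salt-and-pepper noise.  Epoch-2 classes are
drawn per pixel from the row of the transition matrix belonging to the
pixel's epoch-1 class.

The default scene mirrors a small estuarine wetland: four cover classes
(water, mangrove, bare/built-up, other vegetation) with fractions taken
from a ~6400-ha coastal study area, 25-m pixels, a mangrove decade
retention near 83% (a loss of roughly 17%), and DEM heights uniform on
3.71-7.48 m so that the x1.697 canopy model spans a ~6.3-12.7 m maximum
height envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .allometry import WOOD_DENSITY_GCM3, PlotInventory, TreeRecord
from .grids import ClassMap, Grid
from .vulnerability import ShorePoint, sample_shoreline

DEFAULT_LEGEND: tuple[tuple[int, str], ...] = (
    (1, "water"),
    (2, "mangrove"),
    (3, "bare_builtup"),
    (4, "other_vegetation"),
)

#: Epoch-1 class fractions of the default scene (water, mangrove,
#: bare/built-up, other vegetation); they sum to 1.
DEFAULT_FRACTIONS = (0.278, 0.253, 0.058, 0.411)

#: Default decade transition structure: strong persistence, mangrove and
#: other vegetation losing cover to water and bare/built-up.
DEFAULT_TRANSITIONS = (
    (0.97, 0.00, 0.01, 0.02),
    (0.07, 0.83, 0.06, 0.04),
    (0.02, 0.00, 0.93, 0.05),
    (0.04, 0.01, 0.07, 0.88),
)

#: Per-class band signatures (sar_dn, red, nir).  SAR means are raw
#: digital numbers; optical means are surface reflectances.
DEFAULT_BAND_MEANS = (
    (60.0, 0.05, 0.02),
    (1200.0, 0.06, 0.45),
    (350.0, 0.30, 0.28),
    (800.0, 0.09, 0.32),
)
DEFAULT_BAND_SDS = (
    (15.0, 0.01, 0.01),
    (40.0, 0.01, 0.01),
    (25.0, 0.01, 0.01),
    (30.0, 0.01, 0.01),
)
BAND_NAMES = ("sar_dn", "red", "nir")


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene; defaults are the study conditions."""

    width: int = 100
    height: int = 100
    pixel_size: float = 25.0
    class_legend: tuple[tuple[int, str], ...] = DEFAULT_LEGEND
    class_fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    transition_matrix: tuple[tuple[float, ...], ...] = DEFAULT_TRANSITIONS
    band_means: tuple[tuple[float, ...], ...] = DEFAULT_BAND_MEANS
    band_sds: tuple[tuple[float, ...], ...] = DEFAULT_BAND_SDS
    dem_height_range: tuple[float, float] = (3.71, 7.48)
    noise_sd: float = 1.0  # global multiplier on the per-band signature sds
    smooth_sigma: float = 3.0  # pixels; patch scale of the epoch-1 class field
    n_samples: int = 2131
    train_fraction: float = 0.8
    shore_spacing_m: float = 250.0
    n_plots: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def legend(self) -> dict[int, str]:
        return dict(self.class_legend)

    @property
    def codes(self) -> list[int]:
        return [c for c, _ in self.class_legend]

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.pixel_size <= 0:
            raise ValueError("width, height and pixel_size must be positive")
        k = len(self.class_legend)
        fr = np.asarray(self.class_fractions, dtype=float)
        if fr.size != k:
            raise ValueError("class_fractions length does not match legend")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {fr.sum()}, expected 1")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (k, k):
            raise ValueError(f"transition_matrix must be {k}x{k}")
        for i, row in enumerate(tm):
            if (row < 0).any() or abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"transition_matrix row {i} ({self.class_legend[i][1]}) "
                    f"is not a probability vector (sum {row.sum()})"
                )
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        lo, hi = self.dem_height_range
        if not 0 <= lo <= hi:
            raise ValueError("dem_height_range must satisfy 0 <= min <= max")


@dataclass
class SyntheticScene:
    spec: SceneSpec
    lulc_t1: ClassMap
    lulc_t2: ClassMap
    bands_t1: Grid
    bands_t2: Grid
    dem: Grid
    mangrove_mask: Grid
    samples: pd.DataFrame
    inventory: list[PlotInventory]
    shore_points: list[ShorePoint]
    shoreline: LineString


# -- generation steps ----------------------------------------------------


def _epoch1_classes(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Patchy class field: smoothed noise thresholded at fraction quantiles."""
    noise = rng.standard_normal((spec.height, spec.width))
    smooth = ndimage.gaussian_filter(noise, sigma=spec.smooth_sigma) if spec.smooth_sigma else noise
    order = np.argsort(smooth, axis=None)
    n = smooth.size
    counts = np.floor(np.asarray(spec.class_fractions) * n).astype(int)
    counts[-1] += n - counts.sum()  # remainder to the last class
    flat = np.empty(n, dtype=np.int32)
    start = 0
    for code, count in zip(spec.codes, counts):
        flat[order[start : start + count]] = code
        start += count
    return flat.reshape(spec.height, spec.width)


def _epoch2_classes(spec: SceneSpec, codes1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    tm = np.asarray(spec.transition_matrix, dtype=float)
    codes2 = np.empty_like(codes1)
    code_array = np.asarray(spec.codes, dtype=np.int32)
    for i, code in enumerate(spec.codes):
        where = codes1 == code
        codes2[where] = rng.choice(code_array, size=int(where.sum()), p=tm[i])
    return codes2


def _band_stack(spec: SceneSpec, codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    means = np.asarray(spec.band_means)
    sds = np.asarray(spec.band_sds) * spec.noise_sd
    n_bands = means.shape[1]
    stack = np.empty((n_bands, *codes.shape))
    for i, code in enumerate(spec.codes):
        where = codes == code
        n = int(where.sum())
        for b in range(n_bands):
            stack[b][where] = rng.normal(means[i, b], sds[i, b], size=n)
    # SAR digital numbers are nonnegative counts; reflectances stay positive.
    stack[0] = np.clip(stack[0], 1.0, None)
    stack[1:] = np.clip(stack[1:], 1e-4, None)
    return stack


def _inventory(spec: SceneSpec, rng: np.random.Generator) -> list[PlotInventory]:
    """5 m x 5 m plots 25 m apart on a 100-m transect, shoreline outward.

    Tree density and size decline with distance from the shoreline (the
    pattern seen in fringing stands); a plot may be empty.
    """
    species = list(WOOD_DENSITY_GCM3)
    plots = []
    for j in range(spec.n_plots):
        position = 25.0 * j
        lam = max(6.0 * (1.0 - j / spec.n_plots), 0.5)
        n_trees = rng.poisson(lam)
        trees = []
        for _ in range(n_trees):
            dbh = float(np.clip(rng.lognormal(mean=1.0, sigma=0.55), 0.67, 6.48))
            height = float(np.clip(2.0 + 0.65 * dbh + rng.normal(0, 0.4), 2.0, 6.34))
            trees.append(
                TreeRecord(
                    species=str(rng.choice(species)),
                    dbh_cm=round(dbh, 2),
                    height_m=round(height, 2),
                    plot_id=f"plot_{j + 1}",
                )
            )
        plots.append(
            PlotInventory(plot_id=f"plot_{j + 1}", trees=trees, transect_position_m=position)
        )
    return plots


def _shore(
    spec: SceneSpec, mangrove_fraction_by_column: np.ndarray, rng: np.random.Generator
) -> tuple[LineString, list[ShorePoint]]:
    """Sinuous shoreline along the scene's south edge with hazard variables."""
    xs = np.linspace(0, spec.width * spec.pixel_size, 200)
    ys = 100.0 + 60.0 * np.sin(2 * np.pi * xs / (xs[-1] / 3.0))
    line = LineString(np.column_stack([xs, ys]))
    points = sample_shoreline(line, spec.shore_spacing_m)
    n = len(points)
    relief = rng.uniform(0.5, 40.0, size=n)  # m above datum
    wind = rng.weibull(2.0, size=n) * 6.0  # wind-exposure proxy
    wave = rng.weibull(1.8, size=n) * 1.5  # wave-power proxy
    surge = rng.uniform(0.2, 3.0, size=n)  # surge-distance proxy
    geomorph = rng.integers(1, 6, size=n)  # categorical rank lookup 1..5
    for i, p in enumerate(points):
        col = min(
            int(p.x / spec.pixel_size), mangrove_fraction_by_column.size - 1
        )
        p.raw = {
            "geomorphology": float(geomorph[i]),
            "relief": float(relief[i]),
            "habitats": float(mangrove_fraction_by_column[col]),
            "wind": float(wind[i]),
            "wave": float(wave[i]),
            "surge": float(surge[i]),
        }
    return line, points


def generate_scene(spec: SceneSpec | None = None) -> SyntheticScene:
    """Generate the full synthetic scene; deterministic under spec.seed."""
    spec = spec or SceneSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    legend = spec.legend
    mangrove_code = next(c for c, name in spec.class_legend if name == "mangrove")

    codes1 = _epoch1_classes(spec, rng)
    codes2 = _epoch2_classes(spec, codes1, rng)
    lulc_t1 = ClassMap(codes1, legend, spec.pixel_size)
    lulc_t2 = ClassMap(codes2, legend, spec.pixel_size)

    bands_t1 = Grid(_band_stack(spec, codes1, rng), spec.pixel_size)
    bands_t2 = Grid(_band_stack(spec, codes2, rng), spec.pixel_size)

    mask = (codes1 == mangrove_code).astype(float)
    lo, hi = spec.dem_height_range
    dem_values = np.where(mask == 1, rng.uniform(lo, hi, size=codes1.shape), 0.0)
    dem = Grid(dem_values, spec.pixel_size)
    mangrove_mask = Grid(mask, spec.pixel_size)

    samples = sample_points(lulc_t1, spec.n_samples, spec.train_fraction, seed=spec.seed)
    inventory = _inventory(spec, rng)
    shoreline, shore_points = _shore(spec, mask.mean(axis=0), rng)

    return SyntheticScene(
        spec=spec,
        lulc_t1=lulc_t1,
        lulc_t2=lulc_t2,
        bands_t1=bands_t1,
        bands_t2=bands_t2,
        dem=dem,
        mangrove_mask=mangrove_mask,
        samples=samples,
        inventory=inventory,
        shore_points=shore_points,
        shoreline=shoreline,
    )


# -- sampling ------------------------------------------------------------


def sample_points(
    lulc: ClassMap,
    n_total: int = 2131,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified labelled sample points split into train/validation.

    Points are allocated to classes proportionally to their pixel counts
    (largest-remainder rounding) and sampled without replacement.  The
    train split holds floor(n_total x train_fraction) points, allocated
    across classes by largest remainder; the rest validate.  A class with
    no pixels is skipped with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    valid = lulc.valid_mask()
    n_pixels = int(valid.sum())
    if n_total > n_pixels:
        raise ValueError(f"n_total={n_total} exceeds valid pixel count {n_pixels}")
    rng = np.random.default_rng(seed)

    codes = sorted(lulc.legend)
    counts = {c: int(np.count_nonzero(lulc.codes == c)) for c in codes}
    empty = [c for c in codes if counts[c] == 0]
    for c in empty:
        warnings.warn(f"class {lulc.legend[c]!r} has no pixels; skipped in stratification",
                      stacklevel=2)
    codes = [c for c in codes if counts[c] > 0]

    alloc = _largest_remainder(
        np.array([counts[c] for c in codes], dtype=float) / n_pixels, n_total
    )
    alloc = np.minimum(alloc, [counts[c] for c in codes])
    # top up if the cap bit into some class
    deficit = n_total - alloc.sum()
    while deficit > 0:
        room = np.array([counts[c] for c in codes]) - alloc
        i = int(np.argmax(room))
        take = min(deficit, room[i])
        alloc[i] += take
        deficit -= take

    n_train_target = int(np.floor(n_total * train_fraction))
    train_alloc = _largest_remainder(alloc / alloc.sum(), n_train_target)
    train_alloc = np.minimum(train_alloc, alloc)

    frames = []
    for c, n_c, n_tr in zip(codes, alloc, train_alloc):
        rows, cols = np.nonzero(lulc.codes == c)
        pick = rng.choice(rows.size, size=int(n_c), replace=False)
        split = np.full(int(n_c), "validation", dtype=object)
        split[: int(n_tr)] = "train"
        frames.append(
            pd.DataFrame(
                {
                    "row": rows[pick],
                    "col": cols[pick],
                    "class_code": c,
                    "split": split,
                }
            )
        )
    samples = pd.concat(frames, ignore_index=True)
    samples["x"] = (samples["col"] + 0.5) * lulc.pixel_size + lulc.origin[0]
    samples["y"] = lulc.origin[1] - (samples["row"] + 0.5) * lulc.pixel_size
    samples.attrs["n_train"] = int((samples["split"] == "train").sum())
    samples.attrs["n_validation"] = int((samples["split"] == "validation").sum())
    return samples


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` by the largest-remainder method."""
    raw = proportions / proportions.sum() * total
    base = np.floor(raw).astype(int)
    remainder = total - base.sum()
    if remainder > 0:
        order = np.argsort(-(raw - base))
        base[order[:remainder]] += 1
    return base
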