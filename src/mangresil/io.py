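"""Readers and writers for the pipeline's file formats.

Rasters travel as ESRI ASCII grid (``.asc``, single band, plain text) or
TIFF (``.tif``, single or multi band, with pixel size / origin / nodata
carried as JSON in the ImageDescription tag).  Tables (samples, tree
inventories, confusion matrices, exposure results) are CSV; shoreline
points may also round-trip as GeoJSON.  Round-trips preserve values,
nodata and pixel size bit-exactly (``.asc`` to printed precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .accuracy import ConfusionMatrix
from .allometry import PlotInventory, TreeRecord
from .grids import NODATA_CODE, ClassMap, Grid
from .vulnerability import ShorePoint

ASC_NODATA = -9999.0


# -- rasters -------------------------------------------------------------


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a single-band grid as ESRI ASCII."""
    if grid.values.ndim != 2:
        raise ValueError("ESRI ASCII supports single-band grids only; use .tif for stacks")
    rows, cols = grid.shape
    x0, y_top = grid.origin
    values = np.where(np.isfinite(grid.values), grid.values, ASC_NODATA)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {float(x0)!r}\n"
        f"yllcorner {float(y_top - rows * grid.pixel_size)!r}\n"
        f"cellsize {float(grid.pixel_size)!r}\n"
        f"NODATA_value {float(ASC_NODATA)!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ValueError(f"cannot read raster {path}: {exc}") from exc
    meta: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    try:
        cols, rows = int(meta["ncols"]), int(meta["nrows"])
        cellsize = meta["cellsize"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing ASCII-grid header field {exc}") from exc
    values = np.loadtxt(lines[body_start:]).reshape(rows, cols)
    nodata = meta.get("nodata_value", ASC_NODATA)
    values = np.where(values == nodata, np.nan, values)
    x0 = meta.get("xllcorner", 0.0)
    y_top = meta.get("yllcorner", 0.0) + rows * cellsize
    return Grid(values, pixel_size=cellsize, origin=(x0, y_top))


def write_tiff_grid(grid: Grid, path: str | Path) -> None:
    meta = {"pixel_size": grid.pixel_size, "origin": list(grid.origin)}
    tifffile.imwrite(
        path, grid.values, photometric="minisblack", description=json.dumps(meta)
    )


def read_tiff_grid(path: str | Path) -> Grid:
    try:
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read raster {path}: {exc}") from exc
    meta = json.loads(desc) if desc else {}
    return Grid(
        values,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def write_grid(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".asc":
        write_ascii_grid(grid, path)
    elif path.suffix in (".tif", ".tiff"):
        write_tiff_grid(grid, path)
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r} (use .asc or .tif)")


def read_grid(path: str | Path) -> Grid:
    path = Path(path)
    if path.suffix == ".asc":
        return read_ascii_grid(path)
    if path.suffix in (".tif", ".tiff"):
        return read_tiff_grid(path)
    raise ValueError(f"unsupported raster extension {path.suffix!r} (use .asc or .tif)")


def write_class_map(cm: ClassMap, path: str | Path) -> None:
    """Class map as a raster plus a ``.legend.json`` sidecar."""
    grid = Grid(
        np.where(cm.codes == NODATA_CODE, np.nan, cm.codes.astype(float)),
        pixel_size=cm.pixel_size,
        origin=cm.origin,
    )
    write_grid(grid, path)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in cm.legend.items()}, indent=2))


def read_class_map(path: str | Path, legend: dict[int, str] | None = None) -> ClassMap:
    grid = read_grid(path)
    if legend is None:
        sidecar = Path(path).with_suffix(Path(path).suffix + ".legend.json")
        if not sidecar.exists():
            raise ValueError(f"no legend given and no sidecar {sidecar}")
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    codes = np.where(np.isfinite(grid.values), grid.values, NODATA_CODE).astype(np.int32)
    return ClassMap(codes, legend, grid.pixel_size, grid.origin)


# -- tables --------------------------------------------------------------


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_inventory(inventories: list[PlotInventory], path: str | Path) -> None:
    rows = [
        {
            "plot_id": inv.plot_id,
            "species": t.species,
            "dbh_cm": t.dbh_cm,
            "height_m": t.height_m,
            "plot_area_m2": inv.plot_area_m2,
            "transect_position_m": inv.transect_position_m,
        }
        for inv in inventories
        for t in (inv.trees or [None])
        if t is not None
    ]
    # keep empty plots visible as a row with no tree measurements
    for inv in inventories:
        if not inv.trees:
            rows.append(
                {
                    "plot_id": inv.plot_id,
                    "species": "",
                    "dbh_cm": np.nan,
                    "height_m": np.nan,
                    "plot_area_m2": inv.plot_area_m2,
                    "transect_position_m": inv.transect_position_m,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_inventory(path: str | Path) -> list[PlotInventory]:
    df = pd.read_csv(path)
    plots: list[PlotInventory] = []
    for plot_id, group in df.groupby("plot_id", sort=False):
        first = group.iloc[0]
        trees = [
            TreeRecord(
                species=str(r["species"]),
                dbh_cm=float(r["dbh_cm"]),
                height_m=float(r["height_m"]),
                plot_id=str(plot_id),
            )
            for _, r in group.iterrows()
            if pd.notna(r["dbh_cm"])
        ]
        plots.append(
            PlotInventory(
                plot_id=str(plot_id),
                trees=trees,
                plot_area_m2=float(first.get("plot_area_m2", 25.0)),
                transect_position_m=float(first.get("transect_position_m", 0.0)),
            )
        )
    return plots


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    """Header = reference classes; first column = classified classes."""
    cm.to_frame().to_csv(path)


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(df.to_numpy(), tuple(df.columns))


# -- shore points --------------------------------------------------------


def write_shore_points_geojson(points: list[ShorePoint], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": {"id": p.id, **p.raw, **{f"rank_{k}": v for k, v in p.ranks.items()}},
        }
        for p in points
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=2))


def read_shore_points_geojson(path: str | Path) -> list[ShorePoint]:
    data = json.loads(Path(path).read_text())
    points = []
    for feat in data["features"]:
        props = dict(feat["properties"])
        pid = int(props.pop("id"))
        ranks = {k[5:]: int(v) for k, v in props.items() if k.startswith("rank_")}
        raw = {k: float(v) for k, v in props.items() if not k.startswith("rank_")}
        x, y = feat["geometry"]["coordinates"]
        points.append(ShorePoint(id=pid, x=float(x), y=float(y), raw=raw, ranks=ranks))
    return points


def read_shore_points_csv(path: str | Path) -> list[ShorePoint]:
    df = pd.read_csv(path)
    points = []
    for _, r in df.iterrows():
        raw = {
            c: float(r[c])
            for c in df.columns
            if c not in ("id", "x", "y") and not c.startswith("rank_")
        }
        ranks = {c[5:]: int(r[c]) for c in df.columns if c.startswith("rank_")}
        points.append(
            ShorePoint(id=int(r["id"]), x=float(r["x"]), y=float(r["y"]), raw=raw, ranks=ranks)
        )
    return points


# -- config / json -------------------------------------------------------


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
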