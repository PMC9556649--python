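"""Plain-text raster and vector I/O.

Rasters are stored as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
row-major cell values, upper-left first — enough to round-trip the grid
georeference.  The projected CRS identifier travels in a sidecar comment
line, since the classic header has no CRS field.  Vectors are GeoJSON
(already in projected km coordinates) parsed with shapely.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

from .grid import AnalysisGrid, BinaryLayer, ContinuousLayer

NODATA = -9999.0

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_binary_layer",
    "write_continuous_layer",
    "read_binary_layer",
    "read_continuous_layer",
    "read_geojson_geometry",
]


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: AnalysisGrid,
    fmt: str = "%.6g",
) -> None:
    """Write a (n_rows, n_cols) array on ``grid`` as an ESRI ASCII raster."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(values), NODATA, values)
    yll = grid.y_origin - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)
    path.with_suffix(path.suffix + ".crs").write_text(grid.crs + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster; returns (values with NaN no-data, header)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"raster body shape {values.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    crs_file = path.with_suffix(path.suffix + ".crs")
    header["crs"] = crs_file.read_text().strip() if crs_file.exists() else ""
    return values, header


def _grid_from_header(header: dict, mask: np.ndarray) -> AnalysisGrid:
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    return AnalysisGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        study_mask=mask,
        crs=header.get("crs") or "albers-equal-area-km",
    )


def write_binary_layer(path: str | Path, layer: BinaryLayer) -> None:
    vals = layer.values.astype(float).copy()
    vals[~layer.grid.study_mask] = np.nan
    write_ascii_grid(path, vals, layer.grid, fmt="%.0f")


def write_continuous_layer(path: str | Path, layer: ContinuousLayer) -> None:
    write_ascii_grid(path, layer.values, layer.grid, fmt="%.8g")


def read_binary_layer(
    path: str | Path, grid: AnalysisGrid | None = None, name: str = ""
) -> BinaryLayer:
    """Read a 0/1 raster; no-data cells define the mask when no grid given."""
    values, header = read_ascii_grid(path)
    if grid is None:
        grid = _grid_from_header(header, ~np.isnan(values))
    vals = np.nan_to_num(values, nan=0.0)
    if not np.isin(np.unique(vals), (0.0, 1.0)).all():
        raise ValueError(f"{path}: raster is not binary")
    return BinaryLayer(grid=grid, values=vals.astype(np.uint8), name=name)


def read_continuous_layer(
    path: str | Path, grid: AnalysisGrid | None = None, units: str = "", name: str = ""
) -> ContinuousLayer:
    values, header = read_ascii_grid(path)
    if grid is None:
        grid = _grid_from_header(header, ~np.isnan(values))
    return ContinuousLayer(grid=grid, values=values, units=units, name=name)


def read_geojson_geometry(path: str | Path) -> BaseGeometry:
    """Union of all geometries in a GeoJSON file (projected km coordinates)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [geojson_shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [geojson_shape(doc["geometry"])]
    else:
        geoms = [geojson_shape(doc)]
    return shapely.union_all(geoms)
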