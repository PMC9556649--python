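"""Equal-area analysis grid and layer types.

Everything downstream (biodiversity metrics, hotspot rules, gap analysis,
overlap statistics) operates on layers attached to a single
:class:`AnalysisGrid`: a row-major lattice of square cells in a projected
equal-area coordinate system (kilometres), with a boolean study mask that
defines the analysis universe.  Cells outside the mask are excluded from
every statistic.

Geometry is handled by shapely; membership and occupancy rules are *area*
rules (fraction of a cell covered by a polygon), computed by exact polygon
clipping rather than cell-centre sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "AnalysisGrid",
    "BinaryLayer",
    "ContinuousLayer",
    "EmptyStudyAreaError",
    "GridMismatchError",
    "make_grid",
    "coverage_fraction",
    "rasterize_occupancy",
    "aggregate_to_grid",
    "layer_area",
]


class EmptyStudyAreaError(ValueError):
    """The study polygon leaves no cell inside the analysis grid."""


class GridMismatchError(ValueError):
    """Two layers that must share a grid do not."""


@dataclass(frozen=True)
class AnalysisGrid:
    """A row-major lattice of square cells in projected km.

    The origin ``(x_origin, y_origin)`` is the *upper-left* corner of cell
    ``(0, 0)``; row indices increase southward, column indices eastward.
    ``study_mask`` marks the cells that belong to the analysis universe.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x_origin: float
    y_origin: float
    study_mask: np.ndarray
    crs: str = "albers-equal-area-km"

    def __post_init__(self) -> None:
        mask = np.asarray(self.study_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"study_mask shape {mask.shape} != grid shape "
                f"{(self.n_rows, self.n_cols)}"
            )
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not mask.any():
            raise EmptyStudyAreaError("study_mask has no true cell")
        object.__setattr__(self, "study_mask", mask)

    @property
    def cell_area(self) -> float:
        """Area of one cell in km²."""
        return self.cell_size**2

    @property
    def n_mask(self) -> int:
        """Number of cells inside the study area."""
        return int(self.study_mask.sum())

    @property
    def study_area(self) -> float:
        """Total study area in km²."""
        return self.n_mask * self.cell_area

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_polygon(self, row: int, col: int) -> BaseGeometry:
        """Shapely box of one cell, in projected km."""
        x0 = self.x_origin + col * self.cell_size
        y1 = self.y_origin - row * self.cell_size
        return shapely.box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def cell_boxes(self) -> np.ndarray:
        """All cell polygons as a (n_rows, n_cols) object array."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        x0 = self.x_origin + cols * self.cell_size
        y1 = self.y_origin - rows * self.cell_size
        return shapely.box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    def same_geometry(self, other: "AnalysisGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
        )


def _check_same_grid(a, b) -> None:
    if a.grid is not b.grid and not (
        a.grid.same_geometry(b.grid) and np.array_equal(a.grid.study_mask, b.grid.study_mask)
    ):
        raise GridMismatchError("layers are attached to different grids")


@dataclass
class BinaryLayer:
    """A per-cell {0, 1} indicator defined inside the study mask.

    Cells outside the mask are forced to 0 on construction and never enter
    any statistic.
    """

    grid: AnalysisGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise GridMismatchError(
                f"layer shape {vals.shape} != grid shape {self.grid.shape}"
            )
        uniq = np.unique(vals)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"binary layer contains values other than 0/1: {uniq}")
        vals = vals.astype(np.uint8).copy()
        vals[~self.grid.study_mask] = 0
        self.values = vals

    @property
    def n_ones(self) -> int:
        return int(self.values.sum())

    @property
    def prevalence(self) -> float:
        """Fraction of in-mask cells that are 1."""
        return self.n_ones / self.grid.n_mask

    def area(self) -> float:
        return layer_area(self)


@dataclass
class ContinuousLayer:
    """A per-cell real-valued layer with NaN as the missing-data sentinel."""

    grid: AnalysisGrid
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).copy()
        if vals.shape != self.grid.shape:
            raise GridMismatchError(
                f"layer shape {vals.shape} != grid shape {self.grid.shape}"
            )
        vals[~self.grid.study_mask] = np.nan
        self.values = vals

    def masked_values(self) -> np.ndarray:
        """Non-missing values inside the study mask, as a flat array."""
        inside = self.values[self.grid.study_mask]
        return inside[~np.isnan(inside)]


def coverage_fraction(geometry: BaseGeometry, grid: AnalysisGrid) -> np.ndarray:
    """Fraction of each cell's area covered by ``geometry``.

    Exact polygon clipping per cell; cells outside the geometry's bounding
    box are skipped.  Returns a float array of shape ``grid.shape``.
    """
    frac = np.zeros(grid.shape, dtype=float)
    if geometry.is_empty:
        return frac
    minx, miny, maxx, maxy = geometry.bounds
    c0 = max(0, int(math.floor((minx - grid.x_origin) / grid.cell_size)))
    c1 = min(grid.n_cols, int(math.ceil((maxx - grid.x_origin) / grid.cell_size)))
    r0 = max(0, int(math.floor((grid.y_origin - maxy) / grid.cell_size)))
    r1 = min(grid.n_rows, int(math.ceil((grid.y_origin - miny) / grid.cell_size)))
    if c0 >= c1 or r0 >= r1:
        return frac
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    x0 = grid.x_origin + cols * grid.cell_size
    y1 = grid.y_origin - rows * grid.cell_size
    boxes = shapely.box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
    shapely.prepare(geometry)
    inter = shapely.area(shapely.intersection(boxes, geometry))
    frac[r0:r1, c0:c1] = inter / grid.cell_area
    return frac


def make_grid(
    extent: tuple[float, float, float, float],
    cell_size: float,
    study_polygon: BaseGeometry,
    membership_threshold: float = 0.5,
    crs: str = "albers-equal-area-km",
) -> AnalysisGrid:
    """Build the common analysis grid over ``extent`` and mask it.

    Parameters
    ----------
    extent
        ``(xmin, ymin, xmax, ymax)`` in projected km.  The grid covers the
        whole box with whole cells (the last row/column may overhang).
    cell_size
        Cell edge length in km (1 km for the national-scale analysis).
    study_polygon
        The study-area polygon (e.g. a species distribution boundary).
    membership_threshold
        A cell belongs to the study area iff at least this fraction of its
        area is covered by the polygon.  Default 0.5, mirroring the species
        occupancy rule; the source analysis states only that layers were
        clipped to the distribution, not a cell rule.

    Raises
    ------
    EmptyStudyAreaError
        If no cell meets the membership rule.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not 0 < membership_threshold <= 1:
        raise ValueError("membership_threshold must be in (0, 1]")
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    n_cols = int(math.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = int(math.ceil((ymax - ymin) / cell_size - 1e-9))
    # probe geometry before building the mask so an empty intersection fails loudly
    probe = shapely.box(xmin, ymin, xmin + n_cols * cell_size, ymin + n_rows * cell_size)
    if not study_polygon.intersects(probe):
        raise EmptyStudyAreaError("study polygon does not intersect the extent")
    tmp = AnalysisGrid.__new__(AnalysisGrid)
    object.__setattr__(tmp, "n_rows", n_rows)
    object.__setattr__(tmp, "n_cols", n_cols)
    object.__setattr__(tmp, "cell_size", float(cell_size))
    object.__setattr__(tmp, "x_origin", float(xmin))
    object.__setattr__(tmp, "y_origin", float(ymin + n_rows * cell_size))
    object.__setattr__(tmp, "study_mask", np.ones((n_rows, n_cols), dtype=bool))
    object.__setattr__(tmp, "crs", crs)
    frac = coverage_fraction(study_polygon, tmp)
    mask = frac >= membership_threshold - 1e-12
    if not mask.any():
        raise EmptyStudyAreaError("no cell meets the study-area membership rule")
    return AnalysisGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=float(cell_size),
        x_origin=float(xmin),
        y_origin=float(ymin + n_rows * cell_size),
        study_mask=mask,
        crs=crs,
    )


def rasterize_occupancy(
    polygons: BaseGeometry | list[BaseGeometry],
    grid: AnalysisGrid,
    threshold: float = 0.5,
    name: str = "",
) -> BinaryLayer:
    """Rasterize extent-of-occurrence polygons to per-cell occupancy.

    A cell gets 1 iff the fraction of its area covered by the (union of
    the) polygons is at least ``threshold`` and the cell is inside the
    study mask — the ">= 50% of the cell" occupancy rule by default.
    Polygons entirely outside the grid yield an all-zero layer.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(polygons, (list, tuple)):
        geometry = shapely.union_all([g for g in polygons])
    else:
        geometry = polygons
    if not geometry.is_valid:
        geometry = shapely.make_valid(geometry)
        if not geometry.is_valid:
            raise ValueError("invalid geometry could not be repaired")
    frac = coverage_fraction(geometry, grid)
    occ = (frac >= threshold - 1e-12) & grid.study_mask
    return BinaryLayer(grid=grid, values=occ.astype(np.uint8), name=name)


def aggregate_to_grid(fine: ContinuousLayer, grid: AnalysisGrid) -> ContinuousLayer:
    """Generalize a finer-resolution layer onto the analysis grid.

    Each coarse cell takes the area-weighted mean of the fine cells it
    contains (equal-area fine cells, so a plain mean), ignoring missing
    fine cells; a coarse cell whose fine block is entirely missing is
    missing.  The fine grid must align with the coarse grid at an integer
    resolution factor (e.g. 250 m soil-carbon cells under a 1 km grid).
    """
    fg = fine.grid
    factor = grid.cell_size / fg.cell_size
    k = int(round(factor))
    if k < 1 or abs(factor - k) > 1e-9:
        raise ValueError(
            f"fine cell size {fg.cell_size} does not evenly divide coarse "
            f"cell size {grid.cell_size}"
        )
    dx = (fg.x_origin - grid.x_origin) / fg.cell_size
    dy = (grid.y_origin - fg.y_origin) / fg.cell_size
    if abs(dx - round(dx)) > 1e-9 or abs(dy - round(dy)) > 1e-9:
        raise ValueError("fine grid does not align with the coarse grid")
    # fine-cell offset of the coarse origin, in fine cells
    col_off = int(round(-dx))
    row_off = int(round(-dy))
    out = np.full(grid.shape, np.nan)
    fvals = fine.values
    for r in range(grid.n_rows):
        fr0 = r * k + row_off
        fr1 = fr0 + k
        rr0, rr1 = max(fr0, 0), min(fr1, fg.n_rows)
        if rr0 >= rr1:
            continue
        for c in range(grid.n_cols):
            fc0 = c * k + col_off
            fc1 = fc0 + k
            cc0, cc1 = max(fc0, 0), min(fc1, fg.n_cols)
            if cc0 >= cc1:
                continue
            block = fvals[rr0:rr1, cc0:cc1]
            if np.isnan(block).all():
                continue
            out[r, c] = np.nanmean(block)
    if np.isnan(out[grid.study_mask]).all():
        raise ValueError("fine layer has no spatial overlap with the grid")
    return ContinuousLayer(grid=grid, values=out, units=fine.units, name=fine.name)


def layer_area(layer: BinaryLayer) -> float:
    """Total area (km²) of the layer's 1-cells inside the study mask."""
    return float(layer.values[layer.grid.study_mask].sum()) * layer.grid.cell_area
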