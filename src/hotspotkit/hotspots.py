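"""Hotspot delineation: quantile, fixed-threshold and species-union rules.

Five named hotspot layers make up the standard analysis:

========================  =============================================
name                      rule
========================  =============================================
``species_richness``      top quantile (default top quartile, q = 0.75)
``taxonomic_diversity``   top quantile (default q = 0.75)
``unique_species``        union of the unique species' occupancy
``climate_refugia``       refugia index >= 0.0313 (100 km/century
                          dispersal cut on the backward-climate-velocity
                          index)
``soil_carbon``           soil carbon >= 608 t/ha (highest observed 1-m
                          soil carbon density class; ~75th percentile of
                          boreal soil carbon)
========================  =============================================

Quantile convention: the cut is the smallest *data value* v such that at
least a fraction q of cells are <= v (inverse CDF), and cells with value
>= v are hotspot cells — so ties at the cut are all included and hotspot
coverage is at least 1 - q.  Quantiles are computed over all in-mask,
non-missing cells *including zeros* by default; ``include_zeros=False``
restricts to positive cells (this choice materially moves the cut for
sparse metrics, so the realized threshold is always recorded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BinaryLayer, ContinuousLayer, GridMismatchError, layer_area
from .metrics import CellMetrics

__all__ = [
    "DEFAULT_REFUGIA_THRESHOLD",
    "DEFAULT_CARBON_THRESHOLD",
    "HOTSPOT_NAMES",
    "HotspotRule",
    "HotspotLayer",
    "HotspotConfig",
    "DegenerateMetricError",
    "quantile_hotspot",
    "threshold_hotspot",
    "delineate_all",
    "delineation_report",
]

#: Backward-climate-velocity value corresponding to 100 km/century dispersal.
DEFAULT_REFUGIA_THRESHOLD = 0.0313
#: Soil carbon density cut in tonnes/ha (1-m depth).
DEFAULT_CARBON_THRESHOLD = 608.0

HOTSPOT_NAMES = (
    "species_richness",
    "taxonomic_diversity",
    "unique_species",
    "climate_refugia",
    "soil_carbon",
)


class DegenerateMetricError(ValueError):
    """The metric is constant, so a quantile cut cannot separate cells."""


@dataclass(frozen=True)
class HotspotRule:
    """The rule that produced a hotspot layer."""

    kind: str  # top_quantile | fixed_threshold | species_union
    parameter: float | None = None  # quantile fraction or threshold value
    units: str = ""
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.kind == "top_quantile" and not (0 < self.parameter < 1):
            raise ValueError("quantile fraction must be in (0, 1)")
        if self.kind == "fixed_threshold" and not np.isfinite(self.parameter):
            raise ValueError("threshold must be finite")


@dataclass
class HotspotLayer:
    """A named binary hotspot plus the rule and realized cut that made it."""

    name: str
    layer: BinaryLayer
    rule: HotspotRule
    realized_threshold: float | None = None

    @property
    def area(self) -> float:
        return layer_area(self.layer)

    @property
    def prevalence(self) -> float:
        return self.layer.prevalence


@dataclass(frozen=True)
class HotspotConfig:
    """Delineation parameters; defaults are the national-analysis values."""

    q: float = 0.75
    refugia_threshold: float = DEFAULT_REFUGIA_THRESHOLD
    carbon_threshold: float = DEFAULT_CARBON_THRESHOLD
    include_zeros: bool = True


def quantile_hotspot(
    metric: ContinuousLayer,
    q: float = 0.75,
    name: str = "",
    include_zeros: bool = True,
) -> HotspotLayer:
    """Cells at or above the empirical q-quantile of the metric.

    The cut is the type-1 (inverted CDF) sample quantile over in-mask,
    non-missing cells; ties at the cut are all included.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    vals = metric.masked_values()
    if not include_zeros:
        vals = vals[vals != 0]
    if vals.size == 0:
        raise ValueError("metric has no usable cell inside the mask")
    if vals.max() == vals.min():
        raise DegenerateMetricError(
            "metric is constant over the mask; a top-quantile rule cannot "
            "separate cells — use a fixed_threshold rule or check the input"
        )
    cut = float(np.quantile(vals, q, method="inverted_cdf"))
    hot = np.zeros(metric.grid.shape, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        hot[(metric.values >= cut) & metric.grid.study_mask] = 1
    layer = BinaryLayer(grid=metric.grid, values=hot, name=name or metric.name)
    rule = HotspotRule(kind="top_quantile", parameter=q, units=metric.units)
    return HotspotLayer(name=name or metric.name, layer=layer, rule=rule, realized_threshold=cut)


def threshold_hotspot(
    metric: ContinuousLayer, threshold: float, name: str = ""
) -> HotspotLayer:
    """Cells at or above a fixed threshold in the metric's units."""
    hot = np.zeros(metric.grid.shape, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        hot[(metric.values >= threshold) & metric.grid.study_mask] = 1
    layer = BinaryLayer(grid=metric.grid, values=hot, name=name or metric.name)
    rule = HotspotRule(kind="fixed_threshold", parameter=float(threshold), units=metric.units)
    return HotspotLayer(
        name=name or metric.name, layer=layer, rule=rule, realized_threshold=float(threshold)
    )


def delineate_all(
    metrics: CellMetrics,
    unique: BinaryLayer,
    refugia: ContinuousLayer,
    carbon: ContinuousLayer,
    config: HotspotConfig = HotspotConfig(),
) -> list[HotspotLayer]:
    """The five standard hotspot layers, in canonical order."""
    grid = metrics.richness.grid
    for other in (metrics.td.grid, unique.grid, refugia.grid, carbon.grid):
        if not grid.same_geometry(other):
            raise GridMismatchError("all inputs must share the analysis grid")
    richness_h = quantile_hotspot(
        metrics.richness, config.q, "species_richness", config.include_zeros
    )
    td_h = quantile_hotspot(
        metrics.td, config.q, "taxonomic_diversity", config.include_zeros
    )
    unique_h = HotspotLayer(
        name="unique_species",
        layer=BinaryLayer(grid=unique.grid, values=unique.values, name="unique_species"),
        rule=HotspotRule(kind="species_union"),
        realized_threshold=None,
    )
    refugia_h = threshold_hotspot(refugia, config.refugia_threshold, "climate_refugia")
    carbon_h = threshold_hotspot(carbon, config.carbon_threshold, "soil_carbon")
    return [richness_h, td_h, unique_h, refugia_h, carbon_h]


def delineation_report(hotspots: list[HotspotLayer]) -> pd.DataFrame:
    """Tabular summary: rule, realized cut, cell count, area, % of study area."""
    rows = []
    for h in hotspots:
        grid = h.layer.grid
        rows.append(
            {
                "hotspot": h.name,
                "rule": h.rule.kind,
                "parameter": h.rule.parameter,
                "realized_threshold": h.realized_threshold,
                "cells": h.layer.n_ones,
                "area_km2": h.area,
                "percent_of_study_area": 100.0 * h.area / grid.study_area,
            }
        )
    return pd.DataFrame(rows)
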