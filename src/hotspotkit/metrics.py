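"""Biodiversity measures computed from a stack of species occupancy layers.

Three measures, chosen for interpretability:

* **Species richness** — the number of species occupying each cell.
* **Taxonomic diversity (TD)** — a modified inverse Berger–Parker evenness
  index: per-cell richness divided by the species count of the cell's most
  species-rich ("dominant") taxon.  TD is 1 when all species in a cell
  belong to one taxon and grows with taxonomic heterogeneity, bounded by
  the number of taxa present.
* **Unique species** — species whose occupancy is geographically
  restricted (at most ``occupancy_cutoff`` of the study area) while the
  study area holds most of their national extent of occurrence (more than
  ``national_cutoff``); their joint occupancy footprint is the
  unique-species layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import AnalysisGrid, BinaryLayer, ContinuousLayer, GridMismatchError, layer_area

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesRecord",
    "OccupancyStack",
    "CellMetrics",
    "species_richness",
    "taxonomic_diversity",
    "select_unique_species",
    "unique_species_layer",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """Metadata for one at-risk species/subspecies."""

    species_id: str
    taxon: str
    status: str = "other"  # Endangered / Threatened / Special Concern / other
    national_extent_area: float = float("nan")  # km², national extent of occurrence
    within_distribution_area: float = float("nan")  # km², portion inside study area

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError(f"{self.species_id}: taxon label must be non-empty")


@dataclass
class OccupancyStack:
    """Aligned per-species binary layers plus their metadata records."""

    grid: AnalysisGrid
    layers: list[BinaryLayer]
    records: list[SpeciesRecord]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.records):
            raise ValueError("one record per layer required")
        ids = [r.species_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique")
        for layer in self.layers:
            if not layer.grid.same_geometry(self.grid):
                raise GridMismatchError(f"layer {layer.name!r} is on a different grid")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    def occupancy_array(self) -> np.ndarray:
        """(n_species, n_rows, n_cols) uint8 occupancy cube."""
        return np.stack([l.values for l in self.layers]).astype(np.uint8)

    def layer_for(self, species_id: str) -> BinaryLayer:
        try:
            return self.layers[self.species_ids.index(species_id)]
        except ValueError:
            raise KeyError(f"unknown species id {species_id!r}") from None


@dataclass
class CellMetrics:
    """Per-cell richness and taxonomic diversity layers."""

    richness: ContinuousLayer
    td: ContinuousLayer


def species_richness(stack: OccupancyStack) -> ContinuousLayer:
    """Per-cell count of occupying species (0 .. n_species)."""
    if len(stack) == 0:
        raise ValueError("empty occupancy stack")
    total = stack.occupancy_array().sum(axis=0).astype(float)
    return ContinuousLayer(grid=stack.grid, values=total, units="species", name="species_richness")


def taxonomic_diversity(stack: OccupancyStack) -> ContinuousLayer:
    """Per-cell TD = richness / (species count of the dominant taxon).

    Cells with richness 0 take TD = 0 (the 0/0 case): every occupied cell
    has TD >= 1, so empty cells can never enter a top-quantile hotspot.
    """
    if len(stack) == 0:
        raise ValueError("empty occupancy stack")
    cube = stack.occupancy_array()
    taxa = sorted({r.taxon for r in stack.records})
    per_taxon = np.zeros((len(taxa), *stack.grid.shape), dtype=np.int64)
    for t_idx, taxon in enumerate(taxa):
        members = [i for i, r in enumerate(stack.records) if r.taxon == taxon]
        per_taxon[t_idx] = cube[members].sum(axis=0)
    dominant = per_taxon.max(axis=0).astype(float)
    richness = cube.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        td = np.where(richness > 0, richness / dominant, 0.0)
    return ContinuousLayer(grid=stack.grid, values=td, units="ratio", name="taxonomic_diversity")


def select_unique_species(
    stack: OccupancyStack,
    occupancy_cutoff: float = 0.20,
    national_cutoff: float = 0.50,
) -> list[str]:
    """Species both restricted in, and concentrated within, the study area.

    Selects ids with (occupied in-study area / total study area)
    <= ``occupancy_cutoff`` **and** (within-distribution extent / national
    extent) > ``national_cutoff``.  The occupancy share uses the rasterized
    layer area on the analysis grid.  Species with a zero or missing
    national extent are skipped with a warning.
    """
    study_area = stack.grid.study_area
    chosen = []
    for record, layer in zip(stack.records, stack.layers):
        if not record.national_extent_area or np.isnan(record.national_extent_area):
            logger.warning(
                "%s: national extent missing or zero; skipped from uniqueness screen",
                record.species_id,
            )
            continue
        within = record.within_distribution_area
        if np.isnan(within):
            within = layer_area(layer)
        occupancy_share = layer_area(layer) / study_area
        national_share = within / record.national_extent_area
        if occupancy_share <= occupancy_cutoff and national_share > national_cutoff:
            chosen.append(record.species_id)
    return chosen


def unique_species_layer(stack: OccupancyStack, unique_ids: list[str]) -> BinaryLayer:
    """Per-cell union (logical OR) of the selected species' occupancy."""
    values = np.zeros(stack.grid.shape, dtype=np.uint8)
    for sid in unique_ids:
        values |= stack.layer_for(sid).values
    return BinaryLayer(grid=stack.grid, values=values, name="unique_species")
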