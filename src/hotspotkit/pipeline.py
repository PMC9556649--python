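"""End-to-end orchestration: simulate/ingest → metrics → hotspots → gap → overlap.

A single :class:`RunConfig` drives the whole analysis and every output is
reproducible from it: layers are written as ASCII rasters, tables as CSV,
and a plain-text manifest records the config, seeds, package version and a
checksum of every file written.  Re-running an identical config reproduces
identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .gap import GapConfig, gap_analysis, gap_report
from .grid import AnalysisGrid, BinaryLayer, ContinuousLayer
from .hotspots import HotspotConfig, delineate_all, delineation_report
from .metrics import (
    CellMetrics,
    OccupancyStack,
    SpeciesRecord,
    select_unique_species,
    species_richness,
    taxonomic_diversity,
    unique_species_layer,
)
from .overlap import hotspot_count_map, overlap_report, pairwise_table
from .synth import LandscapeConfig, generate_landscape

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "validate_inputs", "load_real_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs.

    ``mode`` is ``"synthetic"`` (landscape generated from ``landscape``)
    or ``"real_data"`` (layers read from ``input_paths``: keys
    ``species_table`` CSV with species_id, taxon, status,
    national_extent_area_km2 and a ``raster`` path column; ``refugia``,
    ``carbon``, ``network`` ASCII rasters; optional ``mask`` raster).
    Exactly one of landscape / input_paths must be populated.
    """

    mode: str = "synthetic"
    landscape: LandscapeConfig | None = field(default_factory=LandscapeConfig)
    input_paths: dict | None = None
    hotspot: HotspotConfig = field(default_factory=HotspotConfig)
    gap: GapConfig = field(default_factory=GapConfig)
    occupancy_cutoff: float = 0.20
    national_cutoff: float = 0.50
    n_permutations: int | None = None
    block_size: int | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real_data"):
            raise ValueError("mode must be 'synthetic' or 'real_data'")
        if self.mode == "synthetic" and self.landscape is None:
            raise ValueError("synthetic mode requires a landscape config")
        if self.mode == "real_data" and not self.input_paths:
            raise ValueError("real_data mode requires input_paths")
        if self.mode == "real_data" and self.landscape is not None:
            object.__setattr__(self, "landscape", None)


@dataclass
class RunReport:
    """All result tables plus the reproducibility manifest."""

    delineation: pd.DataFrame
    gap: pd.DataFrame
    overlap: pd.DataFrame
    overlap_fractions: pd.DataFrame
    unique_ids: list[str]
    manifest: dict


def load_real_inputs(paths: dict) -> tuple[OccupancyStack, ContinuousLayer, ContinuousLayer, BinaryLayer]:
    """Read species stack, refugia, carbon and network from disk."""
    refugia = hio.read_continuous_layer(paths["refugia"], units="index", name="refugia_index")
    grid = refugia.grid
    carbon = hio.read_continuous_layer(paths["carbon"], grid, units="tonnes/ha", name="soil_carbon")
    network = hio.read_binary_layer(paths["network"], grid, name="network")
    table = pd.read_csv(paths["species_table"])
    base = Path(paths["species_table"]).parent
    layers, records = [], []
    for row in table.itertuples(index=False):
        raster = Path(row.raster)
        if not raster.is_absolute():
            raster = base / raster
        layer = hio.read_binary_layer(raster, grid, name=row.species_id)
        layers.append(layer)
        records.append(
            SpeciesRecord(
                species_id=row.species_id,
                taxon=row.taxon,
                status=getattr(row, "status", "other"),
                national_extent_area=float(row.national_extent_area_km2),
                within_distribution_area=layer.area(),
            )
        )
    return OccupancyStack(grid=grid, layers=layers, records=records), refugia, carbon, network


def validate_inputs(
    stack: OccupancyStack,
    refugia: ContinuousLayer,
    carbon: ContinuousLayer,
    network: BinaryLayer,
) -> list[dict]:
    """Pre-flight diagnostics; returns pass/fail checks without running anything."""
    grid = stack.grid
    checks = []

    def add(name: str, passed: bool, message: str) -> None:
        checks.append({"check": name, "passed": bool(passed), "message": message})

    add("mask_nonempty", grid.n_mask > 0, f"{grid.n_mask} study cells")
    for label, layer in (("refugia", refugia), ("carbon", carbon), ("network", network)):
        add(
            f"{label}_grid_aligned",
            grid.same_geometry(layer.grid),
            "grid geometry matches" if grid.same_geometry(layer.grid) else "grid mismatch",
        )
    rv = refugia.masked_values()
    add(
        "refugia_range",
        bool(rv.size and rv.min() >= 0 and rv.max() <= 1),
        f"range [{rv.min():.4g}, {rv.max():.4g}]" if rv.size else "no data",
    )
    cv = carbon.masked_values()
    add(
        "carbon_nonnegative",
        bool(cv.size and cv.min() >= 0),
        f"min {cv.min():.4g} t/ha" if cv.size else "no data",
    )
    missing_taxa = [r.species_id for r in stack.records if not r.taxon]
    add("taxa_complete", not missing_taxa, f"missing taxa: {missing_taxa}" if missing_taxa else "all labelled")
    bad_extent = [
        r.species_id
        for r in stack.records
        if np.isfinite(r.national_extent_area)
        and np.isfinite(r.within_distribution_area)
        and r.within_distribution_area > r.national_extent_area + 2 * grid.cell_area
    ]
    add(
        "extent_consistency",
        not bad_extent,
        f"within > national for: {bad_extent}" if bad_extent else "within <= national",
    )
    return checks


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and (optionally) write all outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.mode == "synthetic":
        scape = generate_landscape(config.landscape)
        stack, refugia, carbon, network = (
            scape.species,
            scape.refugia_index,
            scape.carbon,
            scape.network,
        )
    else:
        stack, refugia, carbon, network = load_real_inputs(config.input_paths)

    diagnostics = validate_inputs(stack, refugia, carbon, network)
    failed = [c for c in diagnostics if not c["passed"]]
    if failed:
        raise RuntimeError(f"input validation failed: {failed}")

    metrics = CellMetrics(
        richness=species_richness(stack), td=taxonomic_diversity(stack)
    )
    unique_ids = select_unique_species(stack, config.occupancy_cutoff, config.national_cutoff)
    unique = unique_species_layer(stack, unique_ids)
    hotspots = delineate_all(metrics, unique, refugia, carbon, config.hotspot)
    for h in hotspots:
        logger.info(
            "hotspot %s: realized cut %s, %d cells (%.2f%% of study area)",
            h.name,
            h.realized_threshold,
            h.layer.n_ones,
            100 * h.area / stack.grid.study_area,
        )
    delineation = delineation_report(hotspots)
    gaps = gap_analysis(hotspots, network, config.gap)
    gap_df = gap_report(gaps)
    overlaps = pairwise_table(
        hotspots, n_permutations=config.n_permutations, seed=config.gap.seed,
        block_size=config.block_size,
    )
    overlap_df = overlap_report(overlaps)
    summary = hotspot_count_map(hotspots)
    fractions = pd.DataFrame(
        {
            "k": list(summary.fraction_exactly),
            "fraction_exactly": list(summary.fraction_exactly.values()),
            "fraction_at_least": list(summary.fraction_at_least.values()),
        }
    )

    manifest: dict = {
        "mode": config.mode,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "diagnostics": diagnostics,
        "unique_species": unique_ids,
        "outputs": {},
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for h in hotspots:
            hio.write_binary_layer(out / f"hotspot_{h.name}.asc", h.layer)
        hio.write_continuous_layer(out / "richness.asc", metrics.richness)
        hio.write_continuous_layer(out / "taxonomic_diversity.asc", metrics.td)
        hio.write_continuous_layer(out / "hotspot_count.asc", summary.count_layer)
        hio.write_binary_layer(out / "network.asc", network)
        delineation.to_csv(out / "delineation.csv", index=False)
        gap_df.to_csv(out / "gap.csv", index=False)
        overlap_df.to_csv(out / "overlap.csv", index=False)
        fractions.to_csv(out / "overlap_fractions.csv", index=False)
        for path in sorted(out.iterdir()):
            if path.is_file() and path.name != "manifest.txt":
                manifest["outputs"][path.name] = _sha256(path)
        with (out / "manifest.txt").open("w") as fh:
            fh.write(json.dumps(manifest, indent=2, default=str))

    return RunReport(
        delineation=delineation,
        gap=gap_df,
        overlap=overlap_df,
        overlap_fractions=fractions,
        unique_ids=unique_ids,
        manifest=manifest,
    )
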