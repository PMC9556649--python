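"""Seeded synthetic landscapes with the spatial structure the analysis assumes.

The generator produces, on one shared grid: spatially autocorrelated binary
species occupancy layers with controllable prevalence and taxon labels; a
right-skewed climate-refugia index in [0, 1]; a log-normal soil-carbon
density field (tonnes/ha); and a protected-network mask of a given size
whose placement can be biased toward or away from a target layer.  It
exists so the whole pipeline — metrics, hotspot rules, gap analysis,
overlap statistics — runs and is testable with no external downloads.

Randomness policy
-----------------
Every output is a pure function of :class:`LandscapeConfig`.  A single
master seed is expanded into independent sub-streams with
``np.random.SeedSequence(master, spawn_key=(stream,))``; the stream ids are
fixed (refugia 0, carbon 1, network 2, taxon assignment 3, prevalence draw
4, species ``i`` at ``1000 + i``) so adding a species never perturbs
previously generated layers.

Default condition
-----------------
Defaults emulate a national-scale at-risk-species analysis across the
boreal caribou distribution: nine taxa with the observed species
composition (birds and fish dominant), a protected network covering
~10.4% of the study area, a refugia index with ~20% of cells above the
0.0313 dispersal cut, and a carbon field with ~36% of cells above
608 tonnes/ha.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, special

from .grid import AnalysisGrid, BinaryLayer, ContinuousLayer

__all__ = [
    "LandscapeConfig",
    "SyntheticLandscape",
    "DEFAULT_TAXA",
    "full_grid",
    "gaussian_field",
    "occupancy_from_field",
    "generate_network",
    "generate_landscape",
]

#: Nine-taxon species composition (weights sum to 80) used by default:
#: birds 27, fish 18, mammals 14, arthropods 7, amphibians 4, plants 4,
#: reptiles 3, lichens 2, molluscs 1.
DEFAULT_TAXA: dict[str, float] = {
    "birds": 27,
    "fish": 18,
    "mammals": 14,
    "arthropods": 7,
    "amphibians": 4,
    "plants": 4,
    "reptiles": 3,
    "lichens": 2,
    "molluscs": 1,
}

_STREAM_REFUGIA = 0
_STREAM_CARBON = 1
_STREAM_NETWORK = 2
_STREAM_TAXA = 3
_STREAM_PREVALENCE = 4
_STREAM_NATIONAL = 5
_STREAM_SPECIES_BASE = 1000


def _rng(master_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class LandscapeConfig:
    """Full parameterization of a synthetic landscape.

    Parameters
    ----------
    seed
        Master seed; the landscape is a pure function of this config.
    n_rows, n_cols, cell_size
        Grid dimensions (cells) and cell edge (km).
    n_species
        Number of binary species layers.
    taxa
        Taxon label -> relative assignment weight (normalized internally).
    prevalence_range
        Per-species target prevalence drawn uniformly from this interval.
    autocorrelation_length
        Gaussian-field correlation scale in km; 0 gives white noise.
    refugia_skew
        Exponent shaping the [0,1] refugia index; larger pushes mass
        toward 0 (sparse refugia).  The default 16 puts ~20% of cells
        above the 0.0313 dispersal threshold.
    carbon_log_mean, carbon_log_sd
        Natural-log parameters of the log-normal carbon field (t/ha);
        defaults put ~36% of cells above 608 t/ha.
    network_fraction
        Fraction of study cells protected (default 0.1043, a network of
        ~10.4% of the study area).
    network_bias
        0 = uniformly random placement; > 0 prefers cells where the target
        layer is high, < 0 prefers cells where it is low.
    network_target
        Name of the bias target: ``"refugia"``, ``"carbon"`` or
        ``"species:<index>"``.  Required when ``network_bias != 0``.
    network_contiguous
        Grow the network as contiguous patches (seeded region-growing)
        instead of independent cells.  Off by default: the gap-analysis
        null is cell-based.
    """

    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1.0
    n_species: int = 30
    taxa: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TAXA))
    prevalence_range: tuple[float, float] = (0.05, 0.6)
    autocorrelation_length: float = 10.0
    refugia_skew: float = 16.0
    carbon_log_mean: float = 6.23
    carbon_log_sd: float = 0.5
    network_fraction: float = 0.1043
    network_bias: float = 0.0
    network_target: str | None = None
    network_contiguous: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("prevalence bounds must lie in (0, 1)")
        if not 0 < self.network_fraction < 1:
            raise ValueError("network_fraction must lie in (0, 1)")
        if self.autocorrelation_length < 0:
            raise ValueError("autocorrelation_length must be >= 0")
        if self.network_bias != 0 and self.network_target is None:
            raise ValueError("network_bias != 0 requires network_target")
        if not self.taxa:
            raise ValueError("taxa must be non-empty")


@dataclass
class SyntheticLandscape:
    """All generated layers on one grid, plus the generating truth."""

    grid: AnalysisGrid
    species: "OccupancyStack"  # noqa: F821 - defined in metrics, imported lazily
    refugia_index: ContinuousLayer
    carbon: ContinuousLayer
    network: BinaryLayer
    truth: dict


def full_grid(n_rows: int, n_cols: int, cell_size: float = 1.0) -> AnalysisGrid:
    """A rectangular grid whose study mask is every cell."""
    return AnalysisGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell_size,
        x_origin=0.0,
        y_origin=n_rows * cell_size,
        study_mask=np.ones((n_rows, n_cols), dtype=bool),
    )


def gaussian_field(
    grid: AnalysisGrid,
    autocorrelation_length: float,
    seed: int | np.random.Generator,
    name: str = "",
) -> ContinuousLayer:
    """A stationary Gaussian random field on the grid.

    White noise smoothed by a periodic Gaussian kernel of scale
    ``autocorrelation_length`` (km), then standardized to zero mean and
    unit variance over the study mask.  Length 0 returns the raw white
    noise (sample moments close to, not exactly, 0/1).  Identical seeds
    give bitwise-identical fields.
    """
    if autocorrelation_length < 0:
        raise ValueError("autocorrelation_length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    if autocorrelation_length == 0:
        return ContinuousLayer(grid=grid, values=white, name=name)
    sigma = autocorrelation_length / grid.cell_size
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    inside = smooth[grid.study_mask]
    sd = inside.std()
    if sd == 0:
        raise ValueError("degenerate field: zero variance after smoothing")
    smooth = (smooth - inside.mean()) / sd
    return ContinuousLayer(grid=grid, values=smooth, name=name)


def occupancy_from_field(
    field_layer: ContinuousLayer, prevalence: float, name: str = ""
) -> BinaryLayer:
    """Threshold a field at its empirical (1 - prevalence) quantile.

    Exactly ``ceil(prevalence * n_mask)`` in-mask cells — the top fraction
    of the field — become 1 (ties broken by cell order, irrelevant for
    continuous fields).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    grid = field_layer.grid
    inside = field_layer.values[grid.study_mask]
    if np.isnan(inside).any():
        raise ValueError("field has missing values inside the mask")
    if inside.max() == inside.min():
        raise ValueError("degenerate field: constant values, quantile undefined")
    k = int(np.ceil(prevalence * inside.size))
    order = np.argsort(inside, kind="stable")[::-1]
    chosen = order[:k]
    flat = np.zeros(inside.size, dtype=np.uint8)
    flat[chosen] = 1
    values = np.zeros(grid.shape, dtype=np.uint8)
    values[grid.study_mask] = flat
    return BinaryLayer(grid=grid, values=values, name=name)


def _contiguous_sample(
    grid: AnalysisGrid, n: int, log_w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Region-growing selection of n in-mask cells; returns flat mask indices.

    Grows patches from random seeds through 4-neighbourhoods, visiting
    frontier cells in order of perturbed log-weight (log w + Gumbel noise),
    so the bias still steers where patches grow.
    """
    mask = grid.study_mask
    rows, cols = np.nonzero(mask)
    flat_of_cell = -np.ones(grid.shape, dtype=np.int64)
    flat_of_cell[rows, cols] = np.arange(rows.size)
    keys = log_w + rng.gumbel(size=log_w.shape)
    selected = np.zeros(rows.size, dtype=bool)
    in_heap = np.zeros(rows.size, dtype=bool)
    heap: list[tuple[float, int]] = []

    def push(r: int, c: int) -> None:
        if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols and mask[r, c]:
            i = flat_of_cell[r, c]
            if not selected[i] and not in_heap[i]:
                in_heap[i] = True
                heapq.heappush(heap, (-keys[i], i))

    start = int(np.argmax(keys))
    push(rows[start], cols[start])
    count = 0
    while count < n:
        if not heap:  # start a new patch at the best unselected cell
            rest = np.where(~selected)[0]
            best = rest[np.argmax(keys[rest])]
            in_heap[best] = True
            heapq.heappush(heap, (-keys[best], best))
        _, i = heapq.heappop(heap)
        if selected[i]:
            continue
        selected[i] = True
        count += 1
        r, c = rows[i], cols[i]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            push(r + dr, c + dc)
    return np.where(selected)[0]


def generate_network(
    grid: AnalysisGrid,
    network_fraction: float,
    network_bias: float = 0.0,
    target: BinaryLayer | ContinuousLayer | None = None,
    seed: int | np.random.Generator = 0,
    contiguous: bool = False,
    name: str = "network",
) -> BinaryLayer:
    """Sample a protected-network mask of ``floor(fraction * n_mask)`` cells.

    Cells are drawn without replacement with weights proportional to
    ``exp(network_bias * target_value)`` (Efraimidis–Spirakis sampling via
    the Gumbel top-k trick); bias 0 is a uniform draw, matching the
    gap-analysis null.
    """
    if not 0 < network_fraction < 1:
        raise ValueError("network_fraction must lie in (0, 1)")
    if network_bias != 0 and target is None:
        raise ValueError("network_bias != 0 requires a target layer")
    n = int(np.floor(network_fraction * grid.n_mask))
    if n < 1:
        raise ValueError("network_fraction selects no cell on this grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target is not None:
        tvals = np.asarray(target.values, dtype=float)[grid.study_mask]
        tvals = np.nan_to_num(tvals, nan=0.0)
        log_w = network_bias * tvals
    else:
        log_w = np.zeros(grid.n_mask)
    if contiguous:
        chosen = _contiguous_sample(grid, n, log_w, rng)
    else:
        keys = log_w + rng.gumbel(size=log_w.shape)
        chosen = np.argpartition(keys, -n)[-n:]
    flat = np.zeros(grid.n_mask, dtype=np.uint8)
    flat[chosen] = 1
    values = np.zeros(grid.shape, dtype=np.uint8)
    values[grid.study_mask] = flat
    return BinaryLayer(grid=grid, values=values, name=name)


def generate_landscape(config: LandscapeConfig) -> SyntheticLandscape:
    """Generate the full bundle: species stack, refugia, carbon, network."""
    from .metrics import OccupancyStack, SpeciesRecord  # circular at module level

    grid = full_grid(config.n_rows, config.n_cols, config.cell_size)
    seed = config.seed

    # refugia: probit transform of a Gaussian field raised to the skew power,
    # so the marginal is Uniform(0,1)**skew — right-skewed, mass near 0
    g_ref = gaussian_field(
        grid, config.autocorrelation_length, _rng(seed, _STREAM_REFUGIA), name="refugia_index"
    )
    u = special.ndtr(g_ref.values)
    refugia = ContinuousLayer(
        grid=grid, values=u**config.refugia_skew, units="index", name="refugia_index"
    )

    g_car = gaussian_field(
        grid, config.autocorrelation_length, _rng(seed, _STREAM_CARBON), name="carbon"
    )
    carbon = ContinuousLayer(
        grid=grid,
        values=np.exp(config.carbon_log_mean + config.carbon_log_sd * g_car.values),
        units="tonnes/ha",
        name="soil_carbon",
    )

    taxon_names = list(config.taxa)
    weights = np.array([config.taxa[t] for t in taxon_names], dtype=float)
    weights /= weights.sum()
    taxa_draw = _rng(seed, _STREAM_TAXA).choice(
        len(taxon_names), size=config.n_species, p=weights
    )
    lo, hi = config.prevalence_range
    prevalences = _rng(seed, _STREAM_PREVALENCE).uniform(lo, hi, size=config.n_species)
    # national fraction inside the study area, used by the unique-species screen
    national_fractions = _rng(seed, _STREAM_NATIONAL).uniform(0.1, 0.9, config.n_species)

    layers, records = [], []
    for i in range(config.n_species):
        sp_field = gaussian_field(
            grid,
            config.autocorrelation_length,
            _rng(seed, _STREAM_SPECIES_BASE + i),
            name=f"sp{i:03d}",
        )
        layer = occupancy_from_field(sp_field, float(prevalences[i]), name=f"sp{i:03d}")
        within = layer.area()
        records.append(
            SpeciesRecord(
                species_id=f"sp{i:03d}",
                taxon=taxon_names[int(taxa_draw[i])],
                status="Threatened",
                national_extent_area=within / float(national_fractions[i]),
                within_distribution_area=within,
            )
        )
        layers.append(layer)
    stack = OccupancyStack(grid=grid, layers=layers, records=records)

    target_layer: BinaryLayer | ContinuousLayer | None = None
    if config.network_target is not None:
        if config.network_target == "refugia":
            target_layer = refugia
        elif config.network_target == "carbon":
            target_layer = carbon
        elif config.network_target.startswith("species:"):
            target_layer = layers[int(config.network_target.split(":", 1)[1])]
        else:
            raise ValueError(f"unknown network_target {config.network_target!r}")
    network = generate_network(
        grid,
        config.network_fraction,
        config.network_bias,
        target_layer,
        _rng(seed, _STREAM_NETWORK),
        contiguous=config.network_contiguous,
    )

    truth = {
        "config": config,
        "taxon_assignment": [taxon_names[int(t)] for t in taxa_draw],
        "target_prevalences": prevalences.tolist(),
        "national_fractions": national_fractions.tolist(),
    }
    return SyntheticLandscape(
        grid=grid,
        species=stack,
        refugia_index=refugia,
        carbon=carbon,
        network=network,
        truth=truth,
    )
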