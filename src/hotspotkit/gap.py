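"""Protected-area gap analysis against a resampling null.

The question: does the protected/conserved-area network contain as much of
each hotspot as a randomly placed network of the same size would?  The
null is built by drawing ``n_samples`` independent random samples of
``network_size`` study cells *without replacement* (each sample the size
of the network), recording each hotspot's area inside every sample, and
summarizing with a mean and a confidence interval.  Observed in-network
area above the CI is over-representation, below it under-representation.

Each draw is without replacement within itself; the draws are mutually
independent — with a network of ~10% of the study cells, drawing all
samples jointly without replacement would exhaust the population after a
handful of samples, so the within-sample reading is the only coherent one.

The closed-form companion: the area of a hotspot of K cells caught by a
uniform without-replacement sample of n cells from N is hypergeometric,
with mean n·K/N and variance n·(K/N)(1−K/N)(N−n)/(N−1).  It serves as an
independent oracle for the resampling null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import AnalysisGrid, BinaryLayer, GridMismatchError
from .hotspots import HotspotLayer

__all__ = [
    "GapConfig",
    "GapResult",
    "observed_in_network",
    "null_distribution",
    "analytic_expectation",
    "classify_representation",
    "gap_analysis",
    "gap_report",
]


@dataclass(frozen=True)
class GapConfig:
    """Resampling-null parameters (defaults: 100 samples, 95% normal CI)."""

    n_samples: int = 100
    ci_level: float = 0.95
    ci_method: str = "normal"  # normal | percentile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.ci_method not in ("normal", "percentile"):
            raise ValueError("ci_method must be 'normal' or 'percentile'")


@dataclass
class GapResult:
    """Observed vs expected in-network hotspot area, with classification."""

    hotspot_name: str
    observed_area: float
    expected_area: float  # null-sample mean
    ci_low: float
    ci_high: float
    analytic_expected_area: float  # hypergeometric mean
    analytic_sd: float
    classification: str = ""


def observed_in_network(hotspot: HotspotLayer, network: BinaryLayer) -> float:
    """Area (km²) of cells that are both hotspot and network."""
    grid = hotspot.layer.grid
    if not grid.same_geometry(network.grid):
        raise GridMismatchError("hotspot and network are on different grids")
    both = hotspot.layer.values & network.values
    return float(both[grid.study_mask].sum()) * grid.cell_area


def null_distribution(
    hotspots: list[HotspotLayer],
    network_size: int,
    grid: AnalysisGrid,
    config: GapConfig = GapConfig(),
) -> dict[str, np.ndarray]:
    """Null samples of in-network area (km²) for each hotspot.

    Each of ``config.n_samples`` draws selects ``network_size`` in-mask
    cells uniformly without replacement; every hotspot's area inside the
    draw is recorded.  Seeded and reproducible.
    """
    if network_size < 1:
        raise ValueError("network_size must be >= 1")
    if network_size > grid.n_mask:
        raise ValueError("network_size exceeds the number of study cells")
    rng = np.random.default_rng(config.seed)
    flats = {h.name: h.layer.values[grid.study_mask].astype(bool) for h in hotspots}
    samples = {name: np.empty(config.n_samples) for name in flats}
    for s in range(config.n_samples):
        idx = rng.choice(grid.n_mask, size=network_size, replace=False)
        for name, flat in flats.items():
            samples[name][s] = flat[idx].sum() * grid.cell_area
    return samples


def analytic_expectation(
    hotspot_area: float,
    network_area: float,
    total_area: float,
    cell_area: float = 1.0,
) -> tuple[float, float]:
    """Hypergeometric mean and sd of in-network hotspot area, in km².

    With N = total cells, K = hotspot cells, n = network cells: mean is
    n·K/N and sd is sqrt(n·(K/N)(1−K/N)(N−n)/(N−1)), scaled by cell area.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if not 0 <= network_area <= total_area:
        raise ValueError("network_area must lie in [0, total_area]")
    N = total_area / cell_area
    K = hotspot_area / cell_area
    n = network_area / cell_area
    mean = n * K / N
    if N <= 1:
        sd = 0.0
    else:
        sd = np.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
    return mean * cell_area, float(sd) * cell_area


def classify_representation(result: GapResult) -> str:
    """over_represented / under_represented / consistent by strict CI exceedance."""
    if result.observed_area > result.ci_high:
        return "over_represented"
    if result.observed_area < result.ci_low:
        return "under_represented"
    return "consistent"


def _ci(values: np.ndarray, level: float, method: str) -> tuple[float, float]:
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        m, sd = values.mean(), values.std(ddof=1)
        return m - z * sd, m + z * sd
    lo = (1 - level) / 2
    return tuple(np.quantile(values, [lo, 1 - lo]))


def gap_analysis(
    hotspots: list[HotspotLayer],
    network: BinaryLayer,
    config: GapConfig = GapConfig(),
) -> list[GapResult]:
    """Full gap analysis of every hotspot against the resampling null."""
    grid = network.grid
    network_size = network.n_ones
    samples = null_distribution(hotspots, network_size, grid, config)
    results = []
    for h in hotspots:
        vals = samples[h.name]
        ci_low, ci_high = _ci(vals, config.ci_level, config.ci_method)
        a_mean, a_sd = analytic_expectation(
            h.area, network_size * grid.cell_area, grid.study_area, grid.cell_area
        )
        res = GapResult(
            hotspot_name=h.name,
            observed_area=observed_in_network(h, network),
            expected_area=float(vals.mean()),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            analytic_expected_area=a_mean,
            analytic_sd=a_sd,
        )
        res.classification = classify_representation(res)
        results.append(res)
    return results


def gap_report(results: list[GapResult]) -> pd.DataFrame:
    """Machine-readable gap table (one row per hotspot)."""
    return pd.DataFrame(
        [
            {
                "hotspot": r.hotspot_name,
                "observed_km2": r.observed_area,
                "expected_km2": r.expected_area,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "analytic_mean_km2": r.analytic_expected_area,
                "classification": r.classification,
            }
            for r in results
        ]
    )
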