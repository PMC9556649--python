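"""Hotspot overlap: per-cell counts and centered Jaccard/Tanimoto statistics.

The raw Jaccard similarity of two binary maps, |A ∩ B| / |A ∪ B|, depends
on the maps' prevalences, so it cannot by itself say whether two hotspots
co-occur more than chance.  The *centered* coefficient subtracts the
expectation under independence at the observed prevalences,

    E[J] = p_a p_b / (p_a + p_b − p_a p_b),

so positive values mean more overlap than chance, negative less, and zero
independence.  A seeded permutation test (random relabelling of one
layer's in-mask cells, optionally in square blocks to respect spatial
autocorrelation) provides finite-sample inference; plain cell permutation
matches the exchangeability assumption of the coefficient itself, and a
note in the report warns that autocorrelation inflates significance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BinaryLayer, ContinuousLayer, GridMismatchError
from .hotspots import HotspotLayer

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapSummary",
    "OverlapResult",
    "hotspot_count_map",
    "jaccard",
    "expected_jaccard_independence",
    "centered_jaccard",
    "permutation_pvalue",
    "pairwise_table",
    "overlap_report",
]


@dataclass
class OverlapSummary:
    """Per-cell hotspot count plus the distribution of counts."""

    count_layer: ContinuousLayer
    fraction_exactly: dict[int, float]
    fraction_at_least: dict[int, float]


@dataclass
class OverlapResult:
    """Centered Jaccard similarity for one hotspot pair."""

    pair: tuple[str, str]
    jaccard: float
    expected_jaccard: float
    centered: float
    p_value: float | None = None
    n_permutations: int | None = None


def hotspot_count_map(hotspots: list[HotspotLayer]) -> OverlapSummary:
    """Sum the hotspot indicators per cell and tabulate the count fractions."""
    if len(hotspots) != 5:
        logger.warning("expected 5 hotspot layers, got %d; proceeding generically", len(hotspots))
    grid = hotspots[0].layer.grid
    for h in hotspots[1:]:
        if not grid.same_geometry(h.layer.grid):
            raise GridMismatchError("hotspots are on different grids")
    counts = np.sum([h.layer.values.astype(np.int64) for h in hotspots], axis=0).astype(float)
    layer = ContinuousLayer(grid=grid, values=counts, units="hotspots", name="hotspot_count")
    inside = counts[grid.study_mask]
    n = inside.size
    kmax = len(hotspots)
    exactly = {k: float((inside == k).sum()) / n for k in range(kmax + 1)}
    at_least = {k: float((inside >= k).sum()) / n for k in range(kmax + 1)}
    return OverlapSummary(count_layer=layer, fraction_exactly=exactly, fraction_at_least=at_least)


def _flat_pair(a: BinaryLayer, b: BinaryLayer) -> tuple[np.ndarray, np.ndarray]:
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError("layers are on different grids")
    mask = a.grid.study_mask
    return a.values[mask].astype(bool), b.values[mask].astype(bool)


def _jaccard_flat(fa: np.ndarray, fb: np.ndarray) -> float:
    union = np.count_nonzero(fa | fb)
    if union == 0:
        logger.warning("both layers empty inside the mask; Jaccard defined as 0")
        return 0.0
    return np.count_nonzero(fa & fb) / union


def jaccard(a: BinaryLayer, b: BinaryLayer) -> float:
    """|A ∩ B| / |A ∪ B| over in-mask cells (0 if both layers are empty)."""
    fa, fb = _flat_pair(a, b)
    return _jaccard_flat(fa, fb)


def expected_jaccard_independence(p_a: float, p_b: float) -> float:
    """Expected Jaccard of independent layers at prevalences p_a, p_b."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise ValueError("prevalences must lie in [0, 1]")
    denom = p_a + p_b - p_a * p_b
    if denom == 0:
        raise ValueError("expected Jaccard undefined for two empty layers")
    return p_a * p_b / denom


def centered_jaccard(
    a: BinaryLayer,
    b: BinaryLayer,
    n_permutations: int | None = None,
    seed: int = 0,
    block_size: int | None = None,
) -> OverlapResult:
    """Observed Jaccard minus its independence expectation.

    Prevalences are computed over the study mask.  When ``n_permutations``
    is given, a two-sided permutation p-value is attached.
    """
    fa, fb = _flat_pair(a, b)
    j = _jaccard_flat(fa, fb)
    expected = expected_jaccard_independence(a.prevalence, b.prevalence)
    result = OverlapResult(
        pair=(a.name, b.name),
        jaccard=j,
        expected_jaccard=expected,
        centered=j - expected,
    )
    if n_permutations is not None:
        result.p_value = permutation_pvalue(a, b, n_permutations, seed, block_size)
        result.n_permutations = n_permutations
    return result


def _permuted(values: np.ndarray, grid, rng, block_size: int | None) -> np.ndarray:
    """Permute a layer's in-mask cells; optionally in square blocks."""
    mask = grid.study_mask
    if block_size is None or block_size <= 1:
        flat = values[mask]
        return rng.permutation(flat)
    # block permutation: move whole block_size x block_size tiles; cells of
    # partial tiles (grid edge or mask boundary) are permuted freely
    arr = np.full(grid.shape, -1, dtype=np.int64)
    arr[mask] = values[mask]
    out = arr.copy()
    blocks = []
    for r0 in range(0, grid.n_rows - block_size + 1, block_size):
        for c0 in range(0, grid.n_cols - block_size + 1, block_size):
            tile_mask = mask[r0 : r0 + block_size, c0 : c0 + block_size]
            if tile_mask.all():
                blocks.append((r0, c0))
    order = rng.permutation(len(blocks))
    for (r0, c0), j in zip(blocks, order):
        rs, cs = blocks[j]
        out[r0 : r0 + block_size, c0 : c0 + block_size] = arr[
            rs : rs + block_size, cs : cs + block_size
        ]
    full = np.zeros(grid.shape, dtype=bool)
    for r0, c0 in blocks:
        full[r0 : r0 + block_size, c0 : c0 + block_size] = True
    loose = mask & ~full
    loose_vals = arr[loose]
    out[loose] = rng.permutation(loose_vals)
    return out[mask]


def permutation_pvalue(
    a: BinaryLayer,
    b: BinaryLayer,
    n_permutations: int = 999,
    seed: int = 0,
    block_size: int | None = None,
) -> float:
    """Two-sided permutation p-value for centered Jaccard ≠ 0.

    Relabels layer b's in-mask cells ``n_permutations`` times (add-one
    corrected), comparing |centered| of each permutation with the observed
    |centered|.  Prevalences are permutation-invariant, so the expectation
    term is constant.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    rng = np.random.default_rng(seed)
    fa, fb = _flat_pair(a, b)
    expected = expected_jaccard_independence(a.prevalence, b.prevalence)
    obs = abs(_jaccard_flat(fa, fb) - expected)
    hits = 0
    bvals = b.values
    for _ in range(n_permutations):
        perm = _permuted(bvals, b.grid, rng, block_size).astype(bool)
        if abs(_jaccard_flat(fa, perm) - expected) >= obs - 1e-15:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def pairwise_table(
    hotspots: list[HotspotLayer],
    n_permutations: int | None = None,
    seed: int = 0,
    block_size: int | None = None,
) -> list[OverlapResult]:
    """Centered Jaccard for every unordered pair, in canonical input order."""
    if len(hotspots) < 2:
        raise ValueError("need at least two hotspot layers")
    results = []
    for k, (ha, hb) in enumerate(itertools.combinations(hotspots, 2)):
        a = BinaryLayer(grid=ha.layer.grid, values=ha.layer.values, name=ha.name)
        b = BinaryLayer(grid=hb.layer.grid, values=hb.layer.values, name=hb.name)
        results.append(
            centered_jaccard(a, b, n_permutations=n_permutations, seed=seed + k, block_size=block_size)
        )
    return results


def overlap_report(results: list[OverlapResult]) -> pd.DataFrame:
    """Tabular pairwise overlap; flags positive-centered pairs.

    Permutation inference assumes cell exchangeability; spatial
    autocorrelation inflates significance, so treat p-values as
    anti-conservative unless a block size was used.
    """
    return pd.DataFrame(
        [
            {
                "hotspot_a": r.pair[0],
                "hotspot_b": r.pair[1],
                "jaccard": r.jaccard,
                "expected_jaccard": r.expected_jaccard,
                "centered": r.centered,
                "positive": r.centered > 0,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
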