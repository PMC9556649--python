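"""Replicate experiments for calibration and power checks.

These functions run the pipeline's stochastic machinery over many seeded
replicate landscapes and summarize calibration (does the resampling-null
CI cover at the nominal rate? is the permutation test's type-I error at
its nominal level?) and power (does a network deliberately biased toward
a hotspot get classified as over-representation?).  They are used by the
test suite and the reproduction script; all sizes default to the
desk-scale study conditions (200×200 grids, 100-sample nulls).
"""

from __future__ import annotations

import numpy as np

from .gap import GapConfig, GapResult, analytic_expectation, classify_representation, gap_analysis
from .grid import layer_area
from .hotspots import HotspotConfig, delineate_all
from .metrics import CellMetrics, select_unique_species, species_richness, taxonomic_diversity, unique_species_layer
from .overlap import centered_jaccard, expected_jaccard_independence
from .synth import (
    LandscapeConfig,
    full_grid,
    gaussian_field,
    generate_landscape,
    generate_network,
    occupancy_from_field,
)

__all__ = [
    "standard_hotspots",
    "null_oracle_check",
    "null_calibration",
    "bias_recovery",
    "centered_null_mean",
    "permutation_type1",
]


def standard_hotspots(config: LandscapeConfig):
    """Generate a landscape and delineate its five standard hotspots."""
    scape = generate_landscape(config)
    metrics = CellMetrics(
        richness=species_richness(scape.species), td=taxonomic_diversity(scape.species)
    )
    unique = unique_species_layer(scape.species, select_unique_species(scape.species))
    hotspots = delineate_all(metrics, unique, scape.refugia_index, scape.carbon, HotspotConfig())
    return scape, hotspots


def null_oracle_check(
    config: LandscapeConfig, gap_config: GapConfig
) -> list[dict]:
    """Compare the resampling-null mean to the hypergeometric closed form.

    Returns one record per hotspot with the null-sample mean, the analytic
    mean and sd, and the Monte-Carlo z-score
    (mean − analytic) / (sd / sqrt(n_samples)).
    """
    scape, hotspots = standard_hotspots(config)
    results = gap_analysis(hotspots, scape.network, gap_config)
    out = []
    for r in results:
        se = r.analytic_sd / np.sqrt(gap_config.n_samples)
        out.append(
            {
                "hotspot": r.hotspot_name,
                "null_mean": r.expected_area,
                "analytic_mean": r.analytic_expected_area,
                "analytic_sd": r.analytic_sd,
                "z": (r.expected_area - r.analytic_expected_area) / se if se > 0 else 0.0,
            }
        )
    return out


def null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    n_rows: int = 200,
    n_cols: int = 200,
    n_species: int = 12,
    ci_level: float = 0.95,
) -> dict:
    """CI coverage of the resampling null under unbiased networks.

    Each replicate generates a fresh landscape with an *unbiased* network,
    runs the gap analysis, and records the classification of every
    hotspot.  Under the null (random network placement) the observed
    in-network area is one more draw from the null distribution, so the
    ``consistent`` rate should sit near ``ci_level``.  Returns the pooled
    rate over all (replicate, hotspot) classifications.
    """
    consistent = 0
    total = 0
    for rep in range(n_replicates):
        config = LandscapeConfig(
            seed=seed * n_replicates + rep,
            n_rows=n_rows,
            n_cols=n_cols,
            n_species=n_species,
            network_bias=0.0,
        )
        scape, hotspots = standard_hotspots(config)
        results = gap_analysis(
            hotspots, scape.network, GapConfig(ci_level=ci_level, seed=config.seed + 1)
        )
        for r in results:
            total += 1
            consistent += r.classification == "consistent"
    return {"consistent_rate": consistent / total, "n": total}


def bias_recovery(
    bias: float,
    n_replicates: int = 100,
    seed: int = 0,
    n_rows: int = 200,
    n_cols: int = 200,
    prevalence: float = 0.25,
    network_fraction: float = 0.10,
    autocorrelation_length: float = 10.0,
) -> dict:
    """Rate at which a biased network is detected by the gap analysis.

    Each replicate builds one hotspot of the given prevalence, samples a
    network biased toward (bias > 0) or away from (bias < 0) it, and
    classifies representation against the 100-sample resampling null.
    Returns the fraction classified ``over_represented`` and
    ``under_represented``.
    """
    from .hotspots import HotspotLayer, HotspotRule

    over = under = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7, rep)))
        grid = full_grid(n_rows, n_cols)
        field = gaussian_field(grid, autocorrelation_length, rng)
        target = occupancy_from_field(field, prevalence, name="target")
        hotspot = HotspotLayer(
            name="target", layer=target, rule=HotspotRule(kind="species_union")
        )
        network = generate_network(grid, network_fraction, bias, target, rng)
        results = gap_analysis(
            [hotspot], network, GapConfig(seed=int(rng.integers(2**31)))
        )
        over += results[0].classification == "over_represented"
        under += results[0].classification == "under_represented"
    return {
        "over_rate": over / n_replicates,
        "under_rate": under / n_replicates,
        "n": n_replicates,
    }


def centered_null_mean(
    n_pairs: int = 100,
    seed: int = 0,
    n_rows: int = 200,
    n_cols: int = 200,
    prevalence_a: float = 0.25,
    prevalence_b: float = 0.25,
    autocorrelation_length: float = 10.0,
) -> dict:
    """Mean centered Jaccard over independently generated layer pairs.

    The two layers of each pair come from independent Gaussian fields, so
    the true association is zero and the mean centered coefficient should
    vanish up to Monte-Carlo error.
    """
    vals = []
    for rep in range(n_pairs):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11, rep)))
        grid = full_grid(n_rows, n_cols)
        a = occupancy_from_field(
            gaussian_field(grid, autocorrelation_length, rng), prevalence_a, name="a"
        )
        b = occupancy_from_field(
            gaussian_field(grid, autocorrelation_length, rng), prevalence_b, name="b"
        )
        vals.append(centered_jaccard(a, b).centered)
    vals = np.asarray(vals)
    return {"mean_centered": float(vals.mean()), "sd": float(vals.std(ddof=1)), "n": n_pairs}


def permutation_type1(
    n_replicates: int = 200,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    n_rows: int = 100,
    n_cols: int = 100,
    prevalence_a: float = 0.3,
    prevalence_b: float = 0.3,
) -> dict:
    """Type-I error of the permutation test on truly independent layers.

    Layers are independent white-noise thresholds (no spatial structure,
    matching the cell-exchangeability assumption), so rejections at level
    alpha should occur at rate alpha.
    """
    from .overlap import permutation_pvalue

    rejections = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(13, rep)))
        grid = full_grid(n_rows, n_cols)
        a = occupancy_from_field(gaussian_field(grid, 0.0, rng), prevalence_a, name="a")
        b = occupancy_from_field(gaussian_field(grid, 0.0, rng), prevalence_b, name="b")
        p = permutation_pvalue(a, b, n_permutations, seed=int(rng.integers(2**31)))
        rejections += p <= alpha
    return {"rejection_rate": rejections / n_replicates, "n": n_replicates}
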