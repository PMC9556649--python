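"""Published national-scale summary used by the worked examples and checks.

Reference areas for the five hotspot types across the boreal caribou
distribution of Canada (a 2,440,837 km² study area on a 1-km equal-area
grid) and inside its protected/conserved-area network (254,646 km², ~10.4%
of the distribution).  These are *inputs* — reported summary areas, not
quantities this package computes; they let the percentage-reporting and
analytic gap machinery be exercised and sanity-checked at national scale
without the underlying rasters.
"""

from __future__ import annotations

import pandas as pd

from .gap import analytic_expectation

__all__ = [
    "TOTAL_DISTRIBUTION_KM2",
    "NETWORK_KM2",
    "NATIONAL_SUMMARY",
    "percent",
    "national_summary_table",
    "analytic_gap_table",
]

TOTAL_DISTRIBUTION_KM2 = 2_440_837.0
NETWORK_KM2 = 254_646.0

#: hotspot -> (total area km², area inside the protected network km²)
NATIONAL_SUMMARY: dict[str, tuple[float, float]] = {
    "species_richness": (613_424.0, 73_491.0),
    "taxonomic_diversity": (425_462.0, 33_196.0),
    "unique_species": (351_587.0, 36_305.0),
    "climate_refugia": (476_720.0, 47_583.0),
    "soil_carbon": (875_376.0, 86_572.0),
}


def percent(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage of ``part`` in ``whole``, rounded for reporting."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)


def national_summary_table() -> pd.DataFrame:
    """The reference summary with reporting percentages attached."""
    rows = []
    for name, (total, in_net) in NATIONAL_SUMMARY.items():
        rows.append(
            {
                "hotspot": name,
                "total_km2": total,
                "percent_of_distribution": percent(total, TOTAL_DISTRIBUTION_KM2),
                "in_network_km2": in_net,
                "percent_of_network": percent(in_net, NETWORK_KM2),
            }
        )
    return pd.DataFrame(rows)


def analytic_gap_table() -> pd.DataFrame:
    """Expected vs observed in-network areas from the reference summary.

    Applies the hypergeometric expectation (random placement of a
    254,646 km² network across the 2,440,837 km² distribution) to each
    hotspot's total area and compares with the reported in-network area.
    Direction only — the resampling CI needs the full rasters.
    """
    rows = []
    for name, (total, in_net) in NATIONAL_SUMMARY.items():
        mean, sd = analytic_expectation(total, NETWORK_KM2, TOTAL_DISTRIBUTION_KM2)
        rows.append(
            {
                "hotspot": name,
                "observed_km2": in_net,
                "analytic_expected_km2": mean,
                "analytic_sd_km2": sd,
                "direction": "over" if in_net > mean else "under",
            }
        )
    return pd.DataFrame(rows)
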