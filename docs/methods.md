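# Methods

`hotspotkit` implements a grid-based conservation co-benefits analysis:
delineate hotspots of at-risk biodiversity, climate refugia and soil
carbon on a common equal-area lattice, ask whether a protected-area
network represents them adequately, and quantify how much the hotspots
overlap one another. This note records the models, the parameter choices
and their rationale, the numerical conventions, and what the synthetic
landscapes do and do not establish.

## The analysis grid

All layers live on one row-major lattice of square cells in a projected
equal-area coordinate system (km), with a boolean study mask defining the
analysis universe; cells outside the mask never enter any statistic. The
reference configuration is a 1 km cell, matching the coarsest input of
the motivating national-scale analysis (the climate-refugia index).

Membership and occupancy are *area* rules computed by exact polygon
clipping, not cell-centre sampling:

* a species occupies a cell iff its extent-of-occurrence polygons cover
  ≥ 50% of the cell's area (`rasterize_occupancy`, threshold
  configurable);
* a cell belongs to the study area iff ≥ 50% of its area falls inside the
  study polygon (`make_grid`, `membership_threshold` configurable). The
  boundary-cell rule is our choice — mirroring the occupancy rule keeps a
  single convention — because clipping alone does not define one.

Finer continuous rasters (e.g. 250 m soil carbon) are generalized to the
analysis grid by the plain mean of the fine cells under each coarse cell
(equal-area cells make the area-weighted mean a plain mean), ignoring
missing fine cells; an all-missing block stays missing. Missing data are
NaN throughout, propagated and never imputed; every hotspot rule treats
missing as "not hotspot".

Raster I/O uses ESRI ASCII grids with an explicit no-data value and a
sidecar CRS identifier; vector input is GeoJSON in projected km. Both are
plain text, diffable and round-trip the georeference.

## Biodiversity measures

With `S` species on the grid, each cell *i* gets:

* **richness** `R_i = Σ_s occ_si`;
* **taxonomic diversity** `TD_i = R_i / max_t n_ti`, where `n_ti` counts
  occupying species of taxon *t* — the inverse Berger–Parker evenness of
  the taxon composition. `TD = 1` when one taxon dominates completely and
  is bounded above by the number of taxa present. Empty cells take
  `TD = 0` (the 0/0 case): every occupied cell has `TD ≥ 1`, so the
  convention can never promote an empty cell into a top-quantile hotspot.
* **unique species**: a species is unique iff its rasterized occupancy is
  ≤ 20% of the study area *and* more than 50% of its national extent of
  occurrence lies inside the study area (inequalities deliberately one
  strict, one not). The ≤ 20% screen is evaluated on the rasterized
  in-mask area, the same footing as every other statistic; polygon-area
  screening can be emulated by supplying `within_distribution_area`
  directly on the species records. The unique-species layer is the
  per-cell union of the selected species.

## Hotspot rules

* Richness and TD hotspots are the **top quartile** (q = 0.75,
  configurable) of in-mask values. The cut is the type-1 / inverted-CDF
  sample quantile — the smallest *data value* v with at least a fraction
  q of cells ≤ v — and cells with value ≥ v are hotspot cells. Data-valued
  cuts make tie handling well defined: ties at the cut are all included,
  so coverage is ≥ 1 − q and can exceed it by the tie mass (with
  integer-valued richness on synthetic grids, coverage of 30–35% is
  normal). Quantiles include zero cells by default; `include_zeros=False`
  is available because zeros dominate sparse metrics and materially move
  the cut — the single most consequential convention in the delineation,
  which is why every report records the realized threshold.
* Climate refugia: index ≥ 0.0313, the backward-climate-velocity value
  corresponding to a 100 km/century dispersal capacity. The constant is
  taken as given; its derivation from a dispersal-weighting function is
  not re-implemented.
* Soil carbon: density ≥ 608 t/ha of 1-m-depth carbon, the highest
  observed soil-type mean in boreal black-spruce systems and roughly the
  75th percentile of boreal soil carbon.
* Unique species: the union layer itself.

A constant metric raises `DegenerateMetricError` rather than returning an
arbitrary all-or-nothing layer.

## Gap analysis

Observed representation is the area of cells that are both hotspot and
network. The null asks what a *randomly placed* network of the same size
would capture: `n_samples` (default 100) independent draws of
`network_size` study cells without replacement, each recording every
hotspot's in-draw area. Each draw is without replacement within itself;
the draws are mutually independent — sampling all draws jointly without
replacement would exhaust a ~10× population after a few draws, so the
within-sample reading is the only coherent one.

The CI (default 95%) is the normal approximation `mean ± z·sd` over the
null sample; a percentile CI is available but crude at 100 samples.
Classification is strict CI exceedance: observed above the upper bound is
over-represented, below the lower bound under-represented, otherwise
consistent. No multiple-testing adjustment is applied across the five
hotspots. The hypergeometric closed form (mean `nK/N`, variance
`n(K/N)(1−K/N)(N−n)/(N−1)`) is computed alongside as an independent
oracle; the resampling mean must sit within Monte-Carlo error of it.

## Overlap statistics

For two binary layers with in-mask prevalences `p_a`, `p_b`, the Jaccard
similarity `J = |A∩B| / |A∪B|` has independence expectation
`E[J] = p_a p_b / (p_a + p_b − p_a p_b)`; the **centered** coefficient
`J − E[J]` is positive when the hotspots co-occur beyond chance. Two empty
layers give `J = 0` by convention (logged) so the 10-pair table never
carries undefined entries. Prevalences are computed over the study mask,
the analysis universe.

The permutation test relabels one layer's in-mask cells (two-sided on
|centered|, add-one estimator, ≥ 99 permutations). Prevalences are
permutation-invariant, so the expectation term is constant and the test
is exact up to the discreteness of the intersection count — which makes
it mildly conservative (empirical type-I ≈ 0.04 at nominal 0.05 on
100×100 grids). Cell permutation assumes exchangeability; spatial
autocorrelation violates it and inflates significance, so p-values on
autocorrelated maps are anti-conservative. A block-permutation option
(square tiles moved whole, partial tiles permuted freely) is provided for
sensitivity analysis, not as a rigorous correction.

## Synthetic landscapes

The generator produces every input the pipeline needs, as a pure function
of a `LandscapeConfig`:

* **Spatial structure**: Gaussian random fields — white noise smoothed by
  a periodic Gaussian kernel of scale `autocorrelation_length` (default
  10 km), standardized to zero mean and unit variance over the mask;
  length 0 is white noise. Species layers threshold independent fields at
  their empirical (1 − prevalence) quantile, so realized prevalence is
  exact to one cell.
* **Defaults as study conditions**: nine taxa with assignment weights
  27:18:14:7:4:4:3:2:1 (birds, fish, mammals, arthropods, amphibians,
  plants, reptiles, lichens, molluscs — the composition of the national
  at-risk species list); per-species prevalence uniform on (0.05, 0.6);
  refugia index `Φ(g)^16`, i.e. Uniform(0,1) raised to skew 16, placing
  ~19.5% of cells above the 0.0313 cut; carbon
  `exp(6.23 + 0.5·g)` t/ha (median ≈ 508), placing ~36% of cells above
  608 t/ha; network fraction 0.1043 of study cells. The refugia and
  carbon marginals were solved once from the target exceedance fractions
  of the national analysis and are not tuned thereafter.
* **Network**: a weighted without-replacement sample (Gumbel top-k /
  Efraimidis–Spirakis) with weights `exp(bias × target)`; bias 0 is
  uniform, matching the gap null, and signed bias provides ground truth
  for recovery experiments. A seeded region-growing `contiguous` option
  exists but is off by default: the gap null is cell-based.
* **Seeding**: one master seed; sub-streams via
  `SeedSequence(master, spawn_key=(stream,))` with fixed stream ids
  (refugia 0, carbon 1, network 2, taxon assignment 3, prevalences 4,
  national fractions 5, species *i* at 1000 + *i*), so adding species
  leaves earlier layers bit-identical.

What the synthetic landscapes do **not** emulate: real extents of
occurrence are contiguous range polygons, not stationary-field excursion
sets; species and taxa are spatially clustered (unique species in the
national analysis cover ~14% of the area jointly, while unions of
independent synthetic layers cover far more); refugia and carbon
correlate with geography and with each other; the real network is a
handful of large contiguous reserves. Passing calibration and recovery
tests therefore establishes that the *statistics* behave correctly under
their stated assumptions — unbiasedness, CI coverage, power — not that
the pipeline's verdicts on any real landscape are insensitive to these
structural differences.

## Problem sizes and determinism

Stochastic checks use 200×200 grids (40,000 cells, the same order as a
1:60 linear downscale of the national grid), 100-sample nulls, and
100–200 replicate landscapes; at these sizes the resampling-null CI
covers at 95.2%, biased networks (|bias| = 2, prevalence 0.25, network
fraction 0.10) are recovered in 100% of replicates, and the centered
Jaccard null mean sits within ±0.002 of zero. Every stochastic routine
takes an explicit seed or generator; pipeline runs are bit-reproducible
from their config, and the run manifest records config, seeds and
per-file SHA-256 checksums.

## Known limitations

* Inputs must already be in an equal-area projection; there is no
  reprojection engine.
* The quantile convention and the zero-inclusion default are choices the
  motivating analysis does not pin down; both are configurable and the
  realized cut is always reported.
* Permutation p-values on autocorrelated maps overstate significance
  (see above).
* No minimum-patch filtering, no reserve-design optimization, no
  IUCN-category stratification of the network.
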