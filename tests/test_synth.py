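"""Determinism, spatial structure and sampling properties of the generator."""

import numpy as np
import pytest
from scipy import ndimage

from hotspotkit import (
    LandscapeConfig,
    full_grid,
    gaussian_field,
    generate_landscape,
    generate_network,
    occupancy_from_field,
)
from hotspotkit.synth import _STREAM_TAXA, _rng, DEFAULT_TAXA


def lag_autocorrelation(values: np.ndarray, lag: int) -> float:
    a = values[:, :-lag].ravel()
    b = values[:, lag:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestGaussianField:
    def test_white_noise_moments(self):
        grid = full_grid(200, 200)
        field = gaussian_field(grid, 0.0, seed=42)
        assert field.values.var() == pytest.approx(1.0, abs=0.05)
        assert field.values.mean() == pytest.approx(0.0, abs=0.05)

    def test_same_seed_bitwise_identical(self):
        grid = full_grid(50, 50)
        a = gaussian_field(grid, 10.0, seed=7)
        b = gaussian_field(grid, 10.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = gaussian_field(grid, 10.0, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_smoothed_field_standardized(self):
        grid = full_grid(120, 120)
        field = gaussian_field(grid, 15.0, seed=3)
        assert field.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert field.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_correlogram_decays(self):
        grid = full_grid(200, 200)
        field = gaussian_field(grid, 10.0, seed=1)
        assert lag_autocorrelation(field.values, 1) > lag_autocorrelation(field.values, 10)
        white = gaussian_field(grid, 0.0, seed=1)
        assert abs(lag_autocorrelation(white.values, 1)) < 0.05

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            gaussian_field(full_grid(5, 5), -1.0, seed=0)


class TestOccupancyFromField:
    def test_exact_prevalence_count(self):
        grid = full_grid(100, 100)
        field = gaussian_field(grid, 5.0, seed=0)
        layer = occupancy_from_field(field, 0.25)
        assert layer.n_ones == 2500

    def test_top_fraction_matches_sorting_oracle(self):
        grid = full_grid(40, 40)
        field = gaussian_field(grid, 8.0, seed=5)
        layer = occupancy_from_field(field, 0.3)
        k = int(np.ceil(0.3 * 1600))
        cut = np.sort(field.values.ravel())[::-1][k - 1]
        np.testing.assert_array_equal(layer.values.astype(bool), field.values >= cut)

    def test_opposite_fields_disjoint(self):
        grid = full_grid(60, 60)
        field = gaussian_field(grid, 6.0, seed=9)
        neg = type(field)(grid=grid, values=-field.values)
        a = occupancy_from_field(field, 0.25)
        b = occupancy_from_field(neg, 0.25)
        assert not (a.values & b.values).any()

    def test_constant_field_rejected(self):
        from hotspotkit import ContinuousLayer

        grid = full_grid(10, 10)
        flat = ContinuousLayer(grid=grid, values=np.full((10, 10), 2.0))
        with pytest.raises(ValueError, match="degenerate"):
            occupancy_from_field(flat, 0.2)

    @pytest.mark.parametrize("prevalence", [0.05, 0.31, 0.77])
    def test_realized_within_one_cell(self, prevalence):
        grid = full_grid(73, 91)  # awkward size to exercise the ceiling
        field = gaussian_field(grid, 4.0, seed=2)
        layer = occupancy_from_field(field, prevalence)
        assert layer.n_ones == int(np.ceil(prevalence * grid.n_mask))


class TestGenerateNetwork:
    def test_size_is_floor_of_fraction(self):
        grid = full_grid(50, 50)
        net = generate_network(grid, 0.1043, seed=0)
        assert net.n_ones == int(np.floor(0.1043 * 2500))

    def test_unbiased_matches_hypergeometric_mean(self):
        grid = full_grid(60, 60)
        field = gaussian_field(grid, 6.0, seed=1)
        target = occupancy_from_field(field, 0.3)
        fractions = []
        for s in range(200):
            net = generate_network(grid, 0.1, 0.0, seed=s)
            inside = (net.values & target.values).sum()
            fractions.append(inside / net.n_ones)
        # hypergeometric: E[in-target fraction] = target prevalence
        se = np.sqrt(0.3 * 0.7 / net.n_ones / 200)  # crude, ignores FPC
        assert np.mean(fractions) == pytest.approx(0.3, abs=5 * se)

    def test_extreme_bias_fills_target(self):
        grid = full_grid(40, 40)
        field = gaussian_field(grid, 4.0, seed=2)
        target = occupancy_from_field(field, 0.3)
        net = generate_network(grid, 0.1, 200.0, target, seed=0)
        assert (net.values & ~target.values.astype(bool)).sum() == 0

    def test_positive_bias_increases_in_target_fraction(self):
        grid = full_grid(60, 60)
        field = gaussian_field(grid, 6.0, seed=3)
        target = occupancy_from_field(field, 0.3)

        def mean_frac(bias):
            vals = []
            for s in range(50):
                net = generate_network(grid, 0.1, bias, target, seed=s)
                vals.append((net.values & target.values).sum() / net.n_ones)
            return np.mean(vals)

        assert mean_frac(2.0) > mean_frac(0.0) + 0.1

    def test_too_small_fraction_fails(self):
        grid = full_grid(10, 10)
        with pytest.raises(ValueError, match="no cell"):
            generate_network(grid, 0.005, seed=0)

    def test_bias_without_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            generate_network(full_grid(10, 10), 0.2, network_bias=1.0, seed=0)

    def test_contiguous_option_produces_fewer_patches(self):
        grid = full_grid(60, 60)
        scattered = generate_network(grid, 0.1, seed=4)
        clumped = generate_network(grid, 0.1, seed=4, contiguous=True)
        assert clumped.n_ones == scattered.n_ones
        _, n_scattered = ndimage.label(scattered.values)
        _, n_clumped = ndimage.label(clumped.values)
        assert n_clumped < n_scattered / 5


class TestGenerateLandscape:
    def test_deterministic_in_config(self):
        config = LandscapeConfig(seed=11, n_rows=60, n_cols=60, n_species=8)
        a = generate_landscape(config)
        b = generate_landscape(config)
        np.testing.assert_array_equal(a.refugia_index.values, b.refugia_index.values)
        np.testing.assert_array_equal(a.carbon.values, b.carbon.values)
        np.testing.assert_array_equal(a.network.values, b.network.values)
        for la, lb in zip(a.species.layers, b.species.layers):
            np.testing.assert_array_equal(la.values, lb.values)
        assert a.truth["taxon_assignment"] == b.truth["taxon_assignment"]

    def test_adding_species_preserves_earlier_layers(self):
        small = generate_landscape(LandscapeConfig(seed=5, n_rows=40, n_cols=40, n_species=4))
        big = generate_landscape(LandscapeConfig(seed=5, n_rows=40, n_cols=40, n_species=6))
        for i in range(4):
            np.testing.assert_array_equal(
                small.species.layers[i].values, big.species.layers[i].values
            )

    def test_taxon_assignment_reproducible_from_seed_stream(self):
        config = LandscapeConfig(seed=3, n_rows=40, n_cols=40, n_species=20)
        scape = generate_landscape(config)
        names = list(DEFAULT_TAXA)
        weights = np.array([DEFAULT_TAXA[t] for t in names], dtype=float)
        weights /= weights.sum()
        draw = _rng(3, _STREAM_TAXA).choice(len(names), size=20, p=weights)
        assert scape.truth["taxon_assignment"] == [names[i] for i in draw]

    def test_field_ranges(self):
        scape = generate_landscape(LandscapeConfig(seed=2, n_rows=50, n_cols=50, n_species=5))
        r = scape.refugia_index.masked_values()
        assert r.min() >= 0 and r.max() <= 1
        assert (scape.carbon.masked_values() > 0).all()

    def test_refugia_right_skewed(self):
        scape = generate_landscape(LandscapeConfig(seed=2, n_rows=100, n_cols=100, n_species=2))
        r = scape.refugia_index.masked_values()
        assert np.median(r) < r.mean()  # long right tail
        assert (r < 0.0313).mean() > 0.5  # most cells below the refugia cut

    def test_prevalence_control(self):
        # realized prevalence is exact to one cell by construction
        config = LandscapeConfig(seed=7, n_rows=100, n_cols=100, n_species=10)
        scape = generate_landscape(config)
        targets = scape.truth["target_prevalences"]
        for layer, target in zip(scape.species.layers, targets):
            realized = layer.prevalence
            assert abs(realized - target) <= 1 / scape.grid.n_mask + 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(network_fraction=1.2)
        with pytest.raises(ValueError):
            LandscapeConfig(prevalence_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            LandscapeConfig(network_bias=1.0)  # no target named
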