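"""Hotspot count maps and centered Jaccard/Tanimoto statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hotspotkit import (
    BinaryLayer,
    HotspotLayer,
    HotspotRule,
    centered_jaccard,
    expected_jaccard_independence,
    full_grid,
    gaussian_field,
    hotspot_count_map,
    jaccard,
    occupancy_from_field,
    overlap_report,
    pairwise_table,
    permutation_pvalue,
)


def binary(grid, values, name="x"):
    return BinaryLayer(grid=grid, values=np.asarray(values).astype(np.uint8), name=name)


def as_hotspot(layer):
    return HotspotLayer(name=layer.name, layer=layer, rule=HotspotRule(kind="species_union"))


class TestCountMap:
    def test_identical_layers(self, grid10, rng):
        vals = rng.random((10, 10)) < 0.3
        layers = [as_hotspot(binary(grid10, vals, f"h{i}")) for i in range(5)]
        summary = hotspot_count_map(layers)
        p = vals.mean()
        assert summary.fraction_exactly[5] == pytest.approx(p)
        assert summary.fraction_exactly[0] == pytest.approx(1 - p)
        for k in (1, 2, 3, 4):
            assert summary.fraction_exactly[k] == 0

    def test_disjoint_layers_max_one(self, grid10):
        layers = []
        for i in range(5):
            vals = np.zeros((10, 10))
            vals[:, 2 * i] = 1
            layers.append(as_hotspot(binary(grid10, vals, f"h{i}")))
        summary = hotspot_count_map(layers)
        assert summary.count_layer.values.max() == 1

    def test_matches_per_cell_tally(self, grid50, rng):
        layers = [
            as_hotspot(binary(grid50, rng.random((50, 50)) < 0.3, f"h{i}")) for i in range(5)
        ]
        summary = hotspot_count_map(layers)
        manual = sum(l.layer.values.astype(int) for l in layers)
        np.testing.assert_array_equal(summary.count_layer.values, manual.astype(float))
        counts = np.bincount(manual.ravel(), minlength=6)
        for k in range(6):
            assert summary.fraction_exactly[k] == pytest.approx(counts[k] / 2500)

    def test_fraction_shapes(self, grid50, rng):
        layers = [
            as_hotspot(binary(grid50, rng.random((50, 50)) < 0.3, f"h{i}")) for i in range(5)
        ]
        s = hotspot_count_map(layers)
        at_least = [s.fraction_at_least[k] for k in range(6)]
        assert all(a >= b for a, b in zip(at_least, at_least[1:]))
        assert sum(s.fraction_exactly.values()) == pytest.approx(1.0)

    def test_nonfive_warns_but_proceeds(self, grid10, rng, caplog):
        layers = [as_hotspot(binary(grid10, rng.random((10, 10)) < 0.4, f"h{i}")) for i in range(3)]
        with caplog.at_level("WARNING"):
            summary = hotspot_count_map(layers)
        assert summary.count_layer.values.max() <= 3
        assert any("expected 5" in r.message for r in caplog.records)


class TestJaccard:
    def test_identical_and_disjoint(self, grid10, rng):
        vals = rng.random((10, 10)) < 0.4
        a = binary(grid10, vals, "a")
        assert jaccard(a, binary(grid10, vals, "b")) == 1.0
        left = np.zeros((10, 10))
        left[:, :4] = 1
        right = np.zeros((10, 10))
        right[:, 6:] = 1
        assert jaccard(binary(grid10, left), binary(grid10, right)) == 0.0

    def test_both_empty_defined_as_zero(self, grid10, caplog):
        empty = binary(grid10, np.zeros((10, 10)))
        with caplog.at_level("WARNING"):
            assert jaccard(empty, binary(grid10, np.zeros((10, 10)))) == 0.0
        assert any("empty" in r.message for r in caplog.records)

    def test_matches_set_oracle(self, grid50, rng):
        va = rng.random((50, 50)) < 0.3
        vb = rng.random((50, 50)) < 0.4
        a_set = set(map(tuple, np.argwhere(va)))
        b_set = set(map(tuple, np.argwhere(vb)))
        expected = len(a_set & b_set) / len(a_set | b_set)
        assert jaccard(binary(grid50, va), binary(grid50, vb)) == pytest.approx(expected)


class TestExpectedJaccard:
    def test_half_half_is_one_third(self):
        assert expected_jaccard_independence(0.5, 0.5) == pytest.approx(1 / 3)

    def test_containment_limit(self):
        assert expected_jaccard_independence(1.0, 0.37) == pytest.approx(0.37)

    def test_both_zero_fails(self):
        with pytest.raises(ValueError):
            expected_jaccard_independence(0.0, 0.0)

    def test_matches_monte_carlo_mean(self, rng):
        p_a, p_b, n_cells, n_rep = 0.3, 0.2, 2500, 400
        grid = full_grid(50, 50)
        sims = []
        for _ in range(n_rep):
            va = rng.random((50, 50)) < p_a
            vb = rng.random((50, 50)) < p_b
            sims.append(jaccard(binary(grid, va), binary(grid, vb)))
        sims = np.asarray(sims)
        se = sims.std(ddof=1) / np.sqrt(n_rep)
        expected = expected_jaccard_independence(p_a, p_b)
        assert abs(sims.mean() - expected) < 4 * se + 1e-3


class TestCenteredJaccard:
    def test_symmetry(self, grid50, rng):
        a = binary(grid50, rng.random((50, 50)) < 0.3, "a")
        b = binary(grid50, rng.random((50, 50)) < 0.4, "b")
        assert centered_jaccard(a, b).centered == centered_jaccard(b, a).centered

    def test_identical_layers_closed_form(self, grid50, rng):
        vals = rng.random((50, 50)) < 0.3
        a = binary(grid50, vals, "a")
        b = binary(grid50, vals, "b")
        p = a.prevalence
        res = centered_jaccard(a, b)
        assert res.centered == pytest.approx(1 - p / (2 - p))
        assert res.centered > 0

    @given(seed=st.integers(0, 500), pa=st.floats(0.05, 0.9), pb=st.floats(0.05, 0.9))
    def test_bounds(self, seed, pa, pb):
        rng = np.random.default_rng(seed)
        grid = full_grid(15, 15)
        a = binary(grid, rng.random((15, 15)) < pa, "a")
        b = binary(grid, rng.random((15, 15)) < pb, "b")
        if a.n_ones == 0 and b.n_ones == 0:
            return
        res = centered_jaccard(a, b)
        assert 0 <= res.jaccard <= 1
        assert -res.expected_jaccard - 1e-12 <= res.centered <= 1 - res.expected_jaccard + 1e-12


class TestPermutationTest:
    def test_identical_layers_minimum_p(self):
        grid = full_grid(30, 30)
        field = gaussian_field(grid, 3.0, seed=1)
        a = occupancy_from_field(field, 0.3, name="a")
        assert permutation_pvalue(a, a, n_permutations=999, seed=0) == pytest.approx(1 / 1000)

    def test_nested_layers_significant(self):
        grid = full_grid(100, 100)
        field = gaussian_field(grid, 5.0, seed=2)
        b = occupancy_from_field(field, 0.4, name="b")
        a = occupancy_from_field(field, 0.2, name="a")  # a is nested in b
        assert (a.values & ~b.values.astype(bool)).sum() == 0
        assert permutation_pvalue(a, b, n_permutations=199, seed=0) < 0.05

    def test_permutation_null_mean_matches_expected_jaccard(self, rng):
        # the independence expectation must agree with the permutation null
        grid = full_grid(50, 50)
        a = binary(grid, rng.random((50, 50)) < 0.3, "a")
        b = binary(grid, rng.random((50, 50)) < 0.4, "b")
        gen = np.random.default_rng(0)
        from hotspotkit.overlap import _permuted

        sims = []
        for _ in range(300):
            perm = _permuted(b.values, b.grid, gen, None).astype(bool)
            fa = a.values[grid.study_mask].astype(bool)
            union = (fa | perm).sum()
            sims.append((fa & perm).sum() / union)
        sims = np.asarray(sims)
        se = sims.std(ddof=1) / np.sqrt(sims.size)
        expected = expected_jaccard_independence(a.prevalence, b.prevalence)
        assert abs(sims.mean() - expected) < 2 * se + 5e-4

    def test_too_few_permutations_rejected(self, grid10, rng):
        a = binary(grid10, rng.random((10, 10)) < 0.5, "a")
        with pytest.raises(ValueError):
            permutation_pvalue(a, a, n_permutations=9)

    def test_block_permutation_runs_and_is_valid(self):
        grid = full_grid(60, 60)
        field = gaussian_field(grid, 8.0, seed=4)
        a = occupancy_from_field(field, 0.3, name="a")
        other = gaussian_field(grid, 8.0, seed=5)
        b = occupancy_from_field(other, 0.3, name="b")
        p = permutation_pvalue(a, b, n_permutations=99, seed=0, block_size=10)
        assert 0 < p <= 1


class TestPairwiseTable:
    def test_ten_rows_for_five_layers(self, grid50, rng):
        layers = [
            as_hotspot(binary(grid50, rng.random((50, 50)) < 0.3, f"h{i}")) for i in range(5)
        ]
        results = pairwise_table(layers)
        assert len(results) == 10
        assert results[0].pair == ("h0", "h1")
        table = overlap_report(results)
        assert table.shape[0] == 10
        assert set(table.columns) >= {"jaccard", "expected_jaccard", "centered", "positive"}

    def test_common_cause_layers_all_positive(self):
        grid = full_grid(80, 80)
        shared = gaussian_field(grid, 8.0, seed=3)
        layers = []
        for i, p in enumerate((0.2, 0.3, 0.4, 0.5)):
            layers.append(as_hotspot(occupancy_from_field(shared, p, name=f"h{i}")))
        results = pairwise_table(layers)
        assert all(r.centered > 0 for r in results)

    def test_fewer_than_two_rejected(self, grid10, rng):
        with pytest.raises(ValueError):
            pairwise_table([as_hotspot(binary(grid10, rng.random((10, 10)) < 0.5))])
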