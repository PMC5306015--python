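"""Landscape metrics against hand geometry and brute-force oracles."""

import numpy as np
import pytest

import farmscape as fs
from farmscape.config import NATURAL, PRODUCTION
from farmscape.landscape_metrics import (
    composition,
    compositional_heterogeneity,
    configurational_heterogeneity,
    label_patches,
)

from .conftest import random_mosaic
from .oracles import config_metrics_oracle, flood_fill_patches


def _mosaic(grid, cell=50.0):
    return fs.LandscapeMosaic(np.asarray(grid), cell)


class TestPatches:
    def test_square_block_geometry(self):
        m = _mosaic(np.full((3, 3), 1))
        (p,) = label_patches(m, NATURAL)
        assert p.cell_count == 9
        assert p.area_ha == pytest.approx(2.25)
        assert p.perimeter_m == pytest.approx(600.0)
        assert p.shape_index == pytest.approx(1.0)

    def test_diagonal_cells_join_under_8_connectivity(self):
        grid = np.array([[1, 0], [0, 1]])
        grid[grid == 0] = 7  # fill buffer with a production category
        assert len(label_patches(_mosaic(grid), NATURAL, connectivity=8)) == 1
        assert len(label_patches(_mosaic(grid), NATURAL, connectivity=4)) == 2

    def test_empty_component_gives_empty_list(self):
        m = _mosaic(np.full((3, 3), 7))
        assert label_patches(m, NATURAL) == []

    @pytest.mark.parametrize("trial", range(20))
    def test_partition_matches_flood_fill_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = random_mosaic(rng, shape=(8, 8), codes=(1, 7))
        for comp, codes in ((NATURAL, {1}), (PRODUCTION, {7})):
            got = label_patches(m, comp)
            want = flood_fill_patches(m.grid, codes)
            got_parts = sorted(
                (p.category, p.cell_count, int(p.perimeter_m / m.cell_size)) for p in got
            )
            want_parts = sorted(
                (p["category"], len(p["cells"]), p["perimeter_edges"]) for p in want
            )
            assert got_parts == want_parts
            # every component cell in exactly one patch
            assert sum(p.cell_count for p in got) == int(np.isin(m.grid, list(codes)).sum())


class TestComposition:
    def test_uniform_buffer(self):
        cov = composition(_mosaic(np.full((4, 4), 7)))
        assert cov[7] == 100.0
        assert all(v == 0.0 for k, v in cov.items() if k != 7)

    def test_half_half(self):
        grid = np.concatenate([np.full((2, 4), 1), np.full((2, 4), 7)])
        cov = composition(_mosaic(grid))
        assert cov[1] == cov[7] == 50.0

    def test_direct_count(self):
        grid = np.full(100, 7)
        grid[:37] = 2
        cov = composition(_mosaic(grid.reshape(10, 10)))
        assert cov[2] == pytest.approx(37.0)

    def test_empty_buffer_raises(self):
        with pytest.raises(ValueError, match="empty buffer"):
            composition(_mosaic(np.zeros((3, 3), dtype=int)))


class TestCompositionalHeterogeneity:
    def test_single_category(self):
        h = compositional_heterogeneity(_mosaic(np.full((3, 3), 1)), NATURAL)
        assert h == {"cover_richness": 1, "cover_diversity": 0.0, "cover_evenness": 0.0}

    def test_two_categories_even_split(self):
        grid = np.concatenate([np.full((2, 4), 1), np.full((2, 4), 2)])
        h = compositional_heterogeneity(_mosaic(grid), NATURAL)
        assert h["cover_diversity"] == pytest.approx(np.log(2))
        assert h["cover_evenness"] == pytest.approx(1.0)

    def test_shannon_direct_evaluation(self):
        # proportions (0.5, 0.3, 0.2) over a 10-cell natural component
        grid = np.array([1] * 5 + [2] * 3 + [3] * 2 + [7] * 6).reshape(4, 4)
        h = compositional_heterogeneity(_mosaic(grid), NATURAL)
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert h["cover_diversity"] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(1.0297, abs=1e-4)

    def test_absent_component_all_zero(self):
        h = compositional_heterogeneity(_mosaic(np.full((3, 3), 7)), NATURAL)
        assert h == {"cover_richness": 0, "cover_diversity": 0.0, "cover_evenness": 0.0}


class TestConfigurationalHeterogeneity:
    def test_line_patch_shape_index(self):
        grid = np.full((4, 4), 7)
        grid[0, :4] = 1  # 1x4 line: perimeter 10 edges, area 4 cells
        h = configurational_heterogeneity(_mosaic(grid), NATURAL)
        assert h["shape_index"] == pytest.approx(0.25 * 10 / 2)

    def test_uniform_buffer_single_patch(self):
        h = configurational_heterogeneity(_mosaic(np.full((5, 5), 7)), PRODUCTION)
        assert h["lpi"] == pytest.approx(100.0)
        assert h["edge_density"] == 0.0

    def test_two_cell_buffer_edge_density(self):
        m = _mosaic(np.array([[1, 7]]), cell=10.0)
        h = configurational_heterogeneity(m, NATURAL)
        # one 10 m edge over 0.02 ha
        assert h["edge_density"] == pytest.approx(500.0)

    def test_absent_component_all_zero(self):
        h = configurational_heterogeneity(_mosaic(np.full((3, 3), 1)), PRODUCTION)
        assert all(v == 0.0 for v in h.values())

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        m = random_mosaic(rng, shape=(10, 10), codes=(1, 2, 6, 7))
        for comp, codes in ((NATURAL, (1, 2)), (PRODUCTION, (6, 7))):
            got = configurational_heterogeneity(m, comp)
            want = config_metrics_oracle(m.grid, codes, m.cell_size)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-10), key


class TestInvariances:
    def _het(self, m):
        out = {}
        for comp in (NATURAL, PRODUCTION):
            out.update({(comp, k): v for k, v in compositional_heterogeneity(m, comp).items()})
            out.update({(comp, k): v for k, v in configurational_heterogeneity(m, comp).items()})
        return out

    def test_category_relabelling_within_component(self, rng):
        m = random_mosaic(rng, shape=(9, 9), codes=(1, 2, 6, 7))
        swapped = m.grid.copy()
        swapped[m.grid == 1], swapped[m.grid == 2] = 2, 1  # permute natural codes
        m2 = fs.LandscapeMosaic(swapped, m.cell_size)
        a, b = self._het(m), self._het(m2)
        for key in a:
            assert a[key] == pytest.approx(b[key]), key

    @pytest.mark.parametrize("op", [np.rot90, np.fliplr, np.flipud])
    def test_rotation_and_mirror_invariance(self, rng, op):
        m = random_mosaic(rng, shape=(9, 9), codes=(1, 2, 6, 7))
        m2 = fs.LandscapeMosaic(op(m.grid).copy(), m.cell_size)
        a, b = self._het(m), self._het(m2)
        for key in a:
            assert a[key] == pytest.approx(b[key]), key

    def test_merging_adjacent_patches_increases_lpi_and_mean_size(self):
        grid = np.full((5, 5), 7)
        grid[0, 0:2] = 1
        grid[0, 3:5] = 1  # two separate 2-cell patches
        before = configurational_heterogeneity(_mosaic(grid), NATURAL)
        grid2 = grid.copy()
        grid2[0, 2] = 1  # bridge them
        after = configurational_heterogeneity(_mosaic(grid2), NATURAL)
        assert after["lpi"] >= before["lpi"]
        assert after["mean_patch_size"] >= before["mean_patch_size"]


def test_metrics_row_has_all_24_variables(study73):
    assert set(fs.ALL_VARIABLES) <= set(study73["metrics"].columns)
    assert len(fs.ALL_VARIABLES) == 24
    m = study73["metrics"]
    # covers in [0, 100] and summing to 100 on gap-free buffers
    cover_cols = [c.name for c in fs.DEFAULT_CATEGORY_MAP.values()]
    sums = m[cover_cols].sum(axis=1)
    assert np.allclose(sums, 100.0)
    assert ((m["nat_cover_evenness"] >= 0) & (m["nat_cover_evenness"] <= 1)).all()
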