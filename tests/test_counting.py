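"""Isolated/touching classification, the area quotient, border merging."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ellipse_mask, single_region, tile_from
from ricescan.counting import (
    CountConfig,
    classify_isolated,
    count_plant,
    count_series,
    count_tile,
    count_touching,
    mean_spikelet_area,
    merge_tile_borders,
)
from ricescan.filters import FilterConfig
from ricescan.segmentation import GrayTile, binarize, denoise, label_regions
from ricescan.synthetic import SceneParams, generate_tile


class TestClassify:
    def test_single_ellipse_is_isolated(self):
        region = single_region(ellipse_mask((60, 60), (30, 30), 16, 7, 0.8))
        isolated, touching = classify_isolated([region], CountConfig())
        assert isolated == [region] and touching == []

    def test_touching_pair_is_touching(self):
        mask = ellipse_mask((90, 90), (45, 30), 7, 16)
        mask |= ellipse_mask((90, 90), (45, 60), 7, 16)
        region = single_region(mask)
        isolated, touching = classify_isolated([region], CountConfig())
        assert touching == [region]

    def test_empty_input(self):
        assert classify_isolated([], CountConfig()) == ([], [])

    def test_partition_exhaustive_exclusive(self, small_params):
        tile, _ = generate_tile(small_params(touching_clusters=(2, 3), seed=8))
        regions = label_regions(denoise(binarize(tile)))
        isolated, touching = classify_isolated(regions, CountConfig())
        assert len(isolated) + len(touching) == len(regions)
        assert set(id(r) for r in isolated).isdisjoint(
            id(r) for r in touching
        )


class TestMeanArea:
    def test_examples(self):
        r100 = single_region(ellipse_mask((30, 30), (15, 15), 8, 4))
        r100.area = 100
        assert mean_spikelet_area([r100]) == 100
        r90, r110 = r100, single_region(ellipse_mask((30, 30), (15, 15), 8, 4))
        r90.area, r110.area = 90, 110
        assert mean_spikelet_area([r90, r110]) == 100

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_spikelet_area([])


class TestAreaQuotient:
    @pytest.mark.parametrize(
        "areas,a_bar,expected",
        [
            ([240.0], 100.0, 2),          # 2.4 A -> 2
            ([150.0], 100.0, 2),          # tie 1.5 rounds away from zero
            ([190.0, 310.0], 100.0, 5),   # 2 + 3
            ([40.0], 100.0, 1),           # clamped to the minimum of 1
        ],
    )
    def test_examples(self, areas, a_bar, expected):
        assert count_touching(areas, a_bar, CountConfig()) == expected

    def test_half_even_tie_rule(self):
        cfg = CountConfig(rounding="half_even")
        assert count_touching([150.0], 100.0, cfg) == 2
        assert count_touching([250.0], 100.0, cfg) == 2

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            count_touching([100.0], 0.0, CountConfig())

    @given(
        st.lists(st.floats(0.6, 8.0), min_size=1, max_size=20),
        st.floats(50.0, 500.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_round_and_sum(self, multiples, a_bar):
        # oracle: direct evaluation of the round-and-sum formula
        areas = [m * a_bar for m in multiples]
        expected = sum(
            max(int(np.floor(a / a_bar + 0.5)), 1) for a in areas
        )
        assert count_touching(areas, a_bar, CountConfig()) == expected


class TestCountTile:
    def test_clean_scene_exact(self, small_params):
        tile, truth = generate_tile(small_params(n_isolated=10, seed=31))
        tc = count_tile(tile)
        assert tc.n == truth.n_kernels == 10
        assert tc.n_isolated == 10 and tc.n_touching == 0

    def test_clusters_counted_by_area(self, small_params):
        p = small_params(tile_height_px=420, tile_width_px=420, n_isolated=6,
                         touching_clusters=(2, 3), seed=37)
        tile, truth = generate_tile(p)
        tc = count_tile(tile)
        assert tc.n == truth.n_kernels == 11
        assert tc.t_regions == 2
        assert tc.n == tc.n_isolated + tc.n_touching

    def test_blank_tile_counts_zero(self):
        tile = GrayTile(np.full((50, 50), 20, dtype=np.uint8))
        assert count_tile(tile).n == 0

    def test_adding_one_kernel_adds_one(self, small_params):
        for n in (4, 5):
            tile, truth = generate_tile(small_params(n_isolated=n, seed=41))
            assert count_tile(tile).n == n


class TestBorderMerge:
    @staticmethod
    def _split(tile, row):
        top = GrayTile(tile.pixels[:row], tile_index=0)
        bottom = GrayTile(tile.pixels[row:], tile_index=1)
        return [top, bottom]

    @pytest.mark.parametrize("seed", range(6))
    def test_split_conservation(self, small_params, seed):
        p = small_params(tile_height_px=400, tile_width_px=400, n_isolated=8,
                         touching_clusters=(2,), seed=seed)
        tile, truth = generate_tile(p)
        whole = count_plant([tile])
        rng = np.random.default_rng(seed)
        halves = self._split(tile, int(rng.integers(100, 300)))
        assert count_plant(halves) == whole == truth.n_kernels

    def test_unmatched_bottom_region_passes_through(self):
        # a kernel merely touching the last row of tile 0; tile 1 is blank
        mask = ellipse_mask((60, 60), (52, 30), 8, 14)
        tiles = [tile_from(mask), GrayTile(np.full((60, 60), 20, np.uint8))]
        tiles[1].tile_index = 1
        assert count_plant(tiles) == 1

    def test_merged_object_counted_in_later_tile(self):
        mask = np.zeros((120, 60), dtype=bool)
        mask |= ellipse_mask((120, 60), (60, 30), 16, 7)  # straddles row 60
        tiles = [
            GrayTile(np.where(mask[:60], 200, 20).astype(np.uint8), 0),
            GrayTile(np.where(mask[60:], 200, 20).astype(np.uint8), 1),
        ]
        sets = [label_regions(binarize(t)) for t in tiles]
        merged = merge_tile_borders(sets, [60, 60])
        assert len(merged[0]) == 0 and len(merged[1]) == 1
        assert merged[1][0].area == int(mask.sum())

    def test_split_cluster_counts_by_merged_area(self, small_params):
        # two abutting kernels cut by the border contribute 2 after merging
        p = small_params(tile_height_px=400, tile_width_px=400, n_isolated=8,
                         touching_clusters=(2,), seed=101)
        tile, truth = generate_tile(p)
        cluster_rows = np.vstack(
            [k.coords for k in truth.kernels if k.cluster_id is not None]
        )[:, 0]
        cut = int(cluster_rows.mean())  # cut through the cluster
        assert count_plant(self._split(tile, cut)) == truth.n_kernels


class TestCountPlant:
    def test_sum_over_clean_tiles(self, small_params):
        tiles = []
        for k in range(5):
            tile, _ = generate_tile(small_params(n_isolated=10, seed=50 + k))
            tile.tile_index = k
            tiles.append(tile)
        assert count_plant(tiles) == 50

    def test_all_blank_series(self):
        tiles = [
            GrayTile(np.full((40, 40), 20, np.uint8), k) for k in range(3)
        ]
        assert count_plant(tiles) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_on_clean_scenes(self, small_params, seed):
        tile, truth = generate_tile(small_params(n_isolated=7, seed=seed))
        assert count_plant([tile]) == truth.n_kernels
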