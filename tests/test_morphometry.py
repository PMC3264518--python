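"""Grain length (max Feret) and grain width (max perpendicular chord)."""
import numpy as np
import pytest
from scipy import ndimage

from conftest import ellipse_mask, single_region
from ricescan.morphometry import (
    grain_length,
    grain_length_endpoints,
    grain_width,
    measure_region,
    plant_grain_stats,
    px_to_mm,
)
from ricescan.segmentation import binarize, label_regions
from ricescan.synthetic import SceneParams, generate_tile


def brute_force_max_distance(points):
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    return d.max()


def rotation_scan_width(mask, p1, p2):
    """Oracle: rotate the mask so the GL chord is horizontal, then scan
    per-column foreground extents."""
    u = np.asarray(p2, float) - np.asarray(p1, float)
    angle_deg = np.degrees(np.arctan2(u[0], u[1]))
    rotated = ndimage.rotate(mask.astype(np.uint8), angle_deg, order=0)
    best = 0.0
    for col in rotated.T:
        rows = np.nonzero(col)[0]
        if rows.size:
            best = max(best, float(rows.max() - rows.min()))
    return best


class TestGrainLength:
    def test_rectangle_diagonal(self):
        pts = np.array([[0, 0], [4, 0], [4, 2], [0, 2]])
        assert grain_length(pts) == pytest.approx(np.sqrt(20))

    def test_two_points(self):
        assert grain_length(np.array([[0, 0], [3, 4]])) == 5

    def test_fewer_than_two_points_errors(self):
        with pytest.raises(ValueError):
            grain_length(np.array([[1, 1]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_fast_path_equals_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(rng.integers(3, 500), 2))
        assert grain_length(pts) == pytest.approx(
            brute_force_max_distance(pts)
        )

    def test_collinear_points(self):
        pts = np.column_stack([np.arange(10), np.arange(10)])
        assert grain_length(pts) == pytest.approx(9 * np.sqrt(2))


class TestGrainWidth:
    def test_rectangle_perpendicular_chord(self):
        # fine lattice approximating the continuous 4 x 2 rectangle
        xs, ys = np.meshgrid(np.arange(0, 4.001, 0.05),
                             np.arange(0, 2.001, 0.05))
        coords = np.column_stack([ys.ravel(), xs.ravel()])
        gl, p1, p2 = grain_length_endpoints(coords)
        assert gl == pytest.approx(np.sqrt(20), abs=0.01)
        assert grain_width(coords, p1, p2, bin_width=0.05) == pytest.approx(
            np.sqrt(5), abs=0.1
        )

    def test_circle_symmetry(self):
        mask = ellipse_mask((50, 50), (25, 25), 15, 15)
        region = single_region(mask)
        gl, p1, p2 = grain_length_endpoints(region.boundary)
        gw = grain_width(region.coords, p1, p2)
        assert gl == pytest.approx(30, abs=1)
        assert gw == pytest.approx(gl, abs=1.5)

    @pytest.mark.parametrize("axes,rot", [((16, 7), 0.0), ((20, 8), 0.7),
                                          ((14, 6), 1.3)])
    def test_rendered_ellipse_axes(self, axes, rot):
        # pixel-center measurements sit ~1 px inside the analytic axes
        # (the renderer excludes the boundary curve itself)
        a, b = axes
        mask = ellipse_mask((80, 80), (40, 40), a, b, rotation=rot)
        region = single_region(mask)
        gl, p1, p2 = grain_length_endpoints(region.boundary)
        gw = grain_width(region.coords, p1, p2)
        assert gl == pytest.approx(2 * a, abs=2.0)
        assert gw == pytest.approx(2 * b, abs=2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_fast_path_matches_rotation_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(10, 20)
        b = rng.uniform(5, a)
        mask = ellipse_mask((70, 70), (35, 35), a, b, rng.uniform(0, np.pi))
        region = single_region(mask)
        _, p1, p2 = grain_length_endpoints(region.boundary)
        fast = grain_width(region.coords, p1, p2)
        oracle = rotation_scan_width(mask, p1, p2)
        assert fast == pytest.approx(oracle, abs=1.0)

    def test_degenerate_collinear_errors(self):
        coords = np.column_stack([np.zeros(10, int), np.arange(10)])
        with pytest.raises(ValueError):
            grain_width(coords, np.array([0, 0]), np.array([0, 9]))


class TestScaleAndOrder:
    @pytest.mark.parametrize("scale", [2.0, 3.5])
    def test_scale_equivariance(self, scale):
        # scaling coordinates and the scan resolution together scales GL/GW
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(60, 2))
        gl, p1, p2 = grain_length_endpoints(pts)
        gl_s, p1_s, p2_s = grain_length_endpoints(pts * scale)
        assert gl_s == pytest.approx(scale * gl)
        assert grain_width(
            pts * scale, p1_s, p2_s, bin_width=scale
        ) == pytest.approx(scale * grain_width(pts, p1, p2), rel=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_gl_at_least_gw(self, seed):
        rng = np.random.default_rng(seed)
        mask = ellipse_mask(
            (60, 60), (30, 30), rng.uniform(8, 18), rng.uniform(4, 8),
            rng.uniform(0, np.pi),
        )
        m = measure_region(single_region(mask))
        assert m.gl_px >= m.gw_px > 0


class TestCalibrationAndStats:
    @pytest.mark.parametrize("px,mmpp,mm", [(31.9, 0.23, 7.337), (0, 0.23, 0),
                                            (14.4, 0.23, 3.312)])
    def test_px_to_mm(self, px, mmpp, mm):
        assert px_to_mm(px, mmpp) == pytest.approx(mm)

    def test_bad_calibration_errors(self):
        with pytest.raises(ValueError):
            px_to_mm(10, 0)

    def test_plant_stats_mean_and_full_sample(self):
        mask_a = ellipse_mask((60, 60), (30, 30), 15.65, 7)
        mask_b = ellipse_mask((60, 60), (30, 30), 16.1, 7.2)
        measures = [measure_region(single_region(m)) for m in (mask_a, mask_b)]
        full = plant_grain_stats(measures)
        sampled = plant_grain_stats(measures, sample_size=2, seed=5)
        assert full == sampled
        assert full[0] == pytest.approx(
            np.mean([m.gl_mm for m in measures])
        )

    def test_sample_larger_than_population_errors(self):
        mask = ellipse_mask((60, 60), (30, 30), 15, 7)
        with pytest.raises(ValueError):
            plant_grain_stats([measure_region(single_region(mask))], 2)

    def test_recovers_generator_axes(self, small_params):
        # oracle: the generator's true axis list, at the default 7.34 mm
        # grain length scale (31.9 px at 0.23 mm/px)
        p = small_params(tile_height_px=600, tile_width_px=600,
                         n_isolated=25, seed=3)
        tile, truth = generate_tile(p)
        regions = label_regions(binarize(tile))  # no median: raw footprints
        measures = [measure_region(r, tile.mm_per_px) for r in regions]
        mean_gl, mean_gw = plant_grain_stats(measures)
        true_gl = truth.kernel_axes_px[:, 0].mean() * tile.mm_per_px
        true_gw = truth.kernel_axes_px[:, 1].mean() * tile.mm_per_px
        assert mean_gl == pytest.approx(true_gl, abs=1.5 * tile.mm_per_px)
        assert mean_gw == pytest.approx(true_gw, abs=1.5 * tile.mm_per_px)
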