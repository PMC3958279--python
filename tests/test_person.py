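"""Anthropometric checks: anchors, scans, metric conversion, IsPerson."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from depthfall.frames import DepthFrame, Stage, SystemConfig
from depthfall.person import (central_superpixel, directional_scan,
                              head_dimensions, head_ground_gap,
                              head_shoulder_gap, is_person, peak_point,
                              pixel_to_mm, check_person)
from depthfall.preprocess import clamp_floor, fill_nulls
from depthfall.simulate import Actor, Furniture, SceneSpec, render_frame


def cf_from(grid):
    return DepthFrame(grid=np.asarray(grid), stage=Stage.CF)


def all_cells():
    return [(r, c) for r in range(40) for c in range(40)]


class TestCentralSuperpixel:
    def test_single_cell(self):
        assert central_superpixel([(3, 7)]) == (3, 7)

    def test_tie_breaks_to_smallest_row(self):
        assert central_superpixel([(2, 4), (3, 4)]) == (2, 4)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cells = [tuple(x) for x in
                     rng.integers(0, 40, size=(int(rng.integers(1, 30)), 2))]
            cells = sorted(set(cells))
            got = central_superpixel(cells)
            arr = np.array(cells, dtype=float)
            mid = arr.mean(axis=0)
            best = min(cells, key=lambda rc: (np.hypot(rc[0] - mid[0],
                                                       rc[1] - mid[1]),
                                              rc[0], rc[1]))
            assert got == best

    def test_empty_blob_rejected(self):
        with pytest.raises(ValueError):
            central_superpixel([])


class TestPixelToMm:
    def test_zero_extent(self, cfg):
        assert pixel_to_mm(0, 1500, "horizontal", cfg) == 0.0

    def test_full_width_at_floor(self, cfg):
        expected = 2 * 3000 * math.tan(math.radians(28.5))
        assert pixel_to_mm(320, 3000, "horizontal", cfg) == pytest.approx(expected)

    def test_full_height_at_floor(self, cfg):
        expected = 2 * 3000 * math.tan(math.radians(21.5))
        assert pixel_to_mm(240, 3000, "vertical", cfg) == pytest.approx(expected)

    @given(st.integers(1, 320), st.integers(200, 7000))
    def test_diagonal_is_pythagorean_combination(self, wp, d):
        cfg = SystemConfig()
        wx = pixel_to_mm(wp, d, "horizontal", cfg)
        wy = pixel_to_mm(wp, d, "vertical", cfg)
        diag = pixel_to_mm(wp, d, "diagonal", cfg)
        assert diag == pytest.approx(math.hypot(wx, wy), rel=1e-12)

    @given(st.integers(1, 100), st.integers(200, 5000),
           st.sampled_from(["horizontal", "vertical"]))
    def test_linear_in_each_argument(self, wp, d, axis):
        cfg = SystemConfig()
        base = pixel_to_mm(wp, d, axis, cfg)
        assert pixel_to_mm(3 * wp, d, axis, cfg) == pytest.approx(3 * base)
        assert pixel_to_mm(wp, 2 * d, axis, cfg) == pytest.approx(2 * base)

    def test_nonpositive_depth_rejected(self, cfg):
        with pytest.raises(ValueError):
            pixel_to_mm(10, 0, "horizontal", cfg)


class TestPeakPoint:
    def test_flat_slab_gives_centroid(self, cfg):
        g = np.full(cfg.frame_shape, 3000, dtype=np.int64)
        cells = [(r, c) for r in range(10, 20) for c in range(10, 20)]
        for r, c in cells:
            g[r * 6:(r + 1) * 6, c * 8:(c + 1) * 8] = 2200
        mp = peak_point(cells, cf_from(g), cfg)
        # footprint rows 60..119, cols 80..159 -> center (89.5, 119.5)
        assert abs(mp[0] - 89.5) <= 1 and abs(mp[1] - 119.5) <= 1

    def test_isolated_single_pixel_peak(self, cfg):
        g = np.full(cfg.frame_shape, 2400, dtype=np.int64)
        g[100, 100] = 2200      # >50 mm above everything else
        cells = all_cells()
        assert peak_point(cells, cf_from(g), cfg) == (100, 100)

    def test_synthetic_head_apex(self, cfg, standing_person_scene):
        spec, frame, cf, gt = standing_person_scene
        rows, cols = np.nonzero(cf.grid == cf.grid.min())
        apex = (rows.mean(), cols.mean())
        cells = all_cells()
        mp = peak_point(cells, cf, cfg)
        assert np.hypot(mp[0] - apex[0], mp[1] - apex[1]) <= 1.5

    def test_empty_blob_rejected(self, cfg):
        with pytest.raises(ValueError):
            peak_point([], cf_from(np.full(cfg.frame_shape, 3000)), cfg)


class TestDirectionalScan:
    def test_uniform_frame_all_zero(self, cfg):
        scan = directional_scan(cf_from(np.full(cfg.frame_shape, 2500)), (120, 160))
        assert all((d == 0).all() for d in scan.diffs.values())

    def test_corner_origin_geometry(self, cfg):
        scan = directional_scan(cf_from(np.full(cfg.frame_shape, 2500)), (0, 0))
        nonempty = {k for k, d in scan.diffs.items() if d.size}
        assert nonempty == {"E", "SE", "S"}
        assert scan.border["W"] == 0 and scan.border["S"] == 239

    def test_mirror_symmetry(self, cfg, standing_person_scene):
        spec, frame, cf, gt = standing_person_scene
        mp = peak_point(all_cells(), cf, cfg)
        scan = directional_scan(cf, mp)
        mirrored = cf_from(cf.grid[:, ::-1].copy())
        mscan = directional_scan(mirrored, (mp[0], 319 - mp[1]))
        np.testing.assert_array_equal(scan.diffs["E"], mscan.diffs["W"])
        np.testing.assert_array_equal(scan.diffs["NE"], mscan.diffs["NW"])


def silhouette_frame(cfg, depth, radius_px=30):
    """A flat disk of the given depth over the floor, centered."""
    g = np.full(cfg.frame_shape, cfg.max_height, dtype=np.int64)
    rr, cc = np.ogrid[:240, :320]
    disk = (rr - 120) ** 2 + (cc - 160) ** 2 <= radius_px ** 2
    g[disk] = depth
    return cf_from(g)


class TestHeadGroundGap:
    def test_standing_silhouette_found(self, cfg):
        cf = silhouette_frame(cfg, 1300)     # step 1700 >= 1300/2
        scan = directional_scan(cf, (120, 160))
        assert head_ground_gap(scan, 1300)

    def test_flat_scene_not_found(self, cfg):
        scan = directional_scan(cf_from(np.full(cfg.frame_shape, 2500)), (120, 160))
        assert not head_ground_gap(scan, 2500)

    def test_low_box_not_found(self, cfg):
        cf = silhouette_frame(cfg, 2600)     # step 400 < 1300
        scan = directional_scan(cf, (120, 160))
        assert not head_ground_gap(scan, 2600)


def head_over_shoulder_frame(cfg, drop, head_r=25, shoulder_r=60,
                             head_depth=1300):
    g = np.full(cfg.frame_shape, cfg.max_height, dtype=np.int64)
    rr, cc = np.ogrid[:240, :320]
    d2 = (rr - 120) ** 2 + (cc - 160) ** 2
    g[d2 <= shoulder_r ** 2] = head_depth + drop
    g[d2 <= head_r ** 2] = head_depth
    return cf_from(g)


class TestHeadShoulderGap:
    def test_head_over_shoulders(self, cfg):
        cf = head_over_shoulder_frame(cfg, drop=250)
        scan = directional_scan(cf, (120, 160))
        assert head_shoulder_gap(scan, cfg) >= 2

    def test_flat_slab_no_directions(self, cfg):
        cf = silhouette_frame(cfg, 2500)
        scan = directional_scan(cf, (120, 160))
        assert head_shoulder_gap(scan, cfg) == 0

    def test_drop_that_skips_the_window(self, cfg):
        # 350 mm straight down overshoots the 200-300 mm head window
        cf = head_over_shoulder_frame(cfg, drop=350)
        scan = directional_scan(cf, (120, 160))
        assert head_shoulder_gap(scan, cfg) == 0


class TestHeadDimensions:
    def test_synthetic_head_recovers_diameter(self, cfg, standing_person_scene):
        spec, frame, cf, gt = standing_person_scene
        check = check_person(all_cells(), cf, cfg)
        dims = check.dimensions
        assert len(dims) == 4
        for v in dims.values():
            assert 200 <= v <= 400
        target = spec.actors[0].head_diameter
        assert max(dims.values()) / min(dims.values()) <= cfg.head_comparability_ratio
        assert abs(np.mean(list(dims.values())) - target) / target < 0.35

    def test_wide_slab_fails(self, cfg):
        # 1200 mm slab at 2,200: E+W extent far beyond the 400 mm bound
        g = np.full(cfg.frame_shape, cfg.max_height, dtype=np.int64)
        g[90:150, 60:260] = 2200
        scan = directional_scan(cf_from(g), (120, 160))
        dims = head_dimensions(scan, 2200, cfg)
        assert dims["E+W"] > 400

    def test_unmet_direction_reports_border_distance(self, cfg):
        g = np.full(cfg.frame_shape, 2500, dtype=np.int64)  # no gap anywhere
        scan = directional_scan(cf_from(g), (120, 160))
        dims = head_dimensions(scan, 2500, cfg)
        expected = pixel_to_mm(320 - 1, 2500, "horizontal", cfg)
        assert dims["E+W"] == pytest.approx(expected)


class TestIsPerson:
    def test_standing_person_accepted(self, cfg, standing_person_scene):
        spec, frame, cf, gt = standing_person_scene
        assert is_person(all_cells(), cf, cfg)

    def test_desk_slab_rejected(self, cfg):
        spec = SceneSpec(furniture=[Furniture(center=(0, 0), size=(800, 500),
                                              height=750)])
        frame, _ = render_frame(spec, 0.0, cfg)
        cf = fill_nulls(clamp_floor(frame, cfg), cfg)
        assert not is_person(all_cells(), cf, cfg)

    def test_floor_only_rejected(self, cfg):
        cf = cf_from(np.full(cfg.frame_shape, cfg.max_height, dtype=np.int64))
        assert not is_person(all_cells(), cf, cfg)

    def test_mirror_invariance(self, cfg, standing_person_scene):
        spec, frame, cf, gt = standing_person_scene
        mirrored = cf_from(cf.grid[:, ::-1].copy())
        assert is_person(all_cells(), cf, cfg) == \
            is_person(all_cells(), mirrored, cfg)

    def test_separates_people_from_furniture_across_scenes(self, cfg):
        """Parameter recovery: persons vs desks/chairs on randomized scenes."""
        rng = np.random.default_rng(17)
        hits = 0
        for i in range(50):
            if i % 2 == 0:
                height = float(rng.uniform(1550, 1900))
                spec = SceneSpec(actors=[Actor(
                    height=height,
                    head_diameter=float(rng.uniform(220, 280)),
                    shoulder_drop=float(rng.uniform(210, 290)),
                    trajectory=[(0.0, float(rng.uniform(-250, 250)),
                                 float(rng.uniform(-200, 200)))])])
                expect = True
            else:
                spec = SceneSpec(furniture=[Furniture(
                    center=(float(rng.uniform(-250, 250)),
                            float(rng.uniform(-200, 200))),
                    size=(float(rng.uniform(350, 900)),
                          float(rng.uniform(350, 700))),
                    height=float(rng.uniform(300, 1000)))])
                expect = False
            frame, _ = render_frame(spec, 0.0, cfg)
            cf = fill_nulls(clamp_floor(frame, cfg), cfg)
            hits += is_person(all_cells(), cf, cfg) == expect
        assert hits == 50
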