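"""Autofocus, stitching, spot detection, isolation, routing, geometry."""

import itertools

import numpy as np
import pytest

from cytoscreen.phantom import ImageTile, generate_slide, render_image
from cytoscreen.targeting import (
    CandidateSet,
    ScanRangeError,
    TargetList,
    VarianceProfile,
    apply_laser_offset,
    autofocus,
    detect_bright_spots,
    fit_pixel_to_stage,
    order_route,
    select_isolated,
    stitch_grid,
    variance_metric,
)


def tile(pixels, stage_xy=(0.0, 0.0), z=0.0, pixel_size=0.5):
    return ImageTile(pixels=np.asarray(pixels, dtype=float),
                     stage_xy=stage_xy, z=z, pixel_size=pixel_size)


class TestVarianceMetric:
    def test_constant_image_is_zero(self):
        assert variance_metric(tile(np.full((8, 8), 7.0))) == 0.0

    def test_two_pixel_hand_computation(self):
        assert variance_metric(tile([[0.0, 2.0]])) == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        img = rng.uniform(1.0, 50.0, size=(40, 50))
        mu = img.sum() / img.size
        var = ((img - mu) ** 2).sum() / img.size
        assert variance_metric(tile(img)) == pytest.approx(var / mu, rel=1e-10)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            variance_metric(np.zeros((4, 4)))


class TestAutofocus:
    def profile(self):
        z = np.arange(-10.0, 21.0, 2.0)
        metric = 2.0 * np.exp(-((z - 14.0) ** 2) / 20.0) + 0.5 * (
            1 - np.exp(-(z**2) / 8.0)
        ) + 0.1
        return VarianceProfile(z=z, metric=metric)

    def test_peak_and_minimum_recovered(self):
        res = autofocus(self.profile())
        assert res.z_bright_spot == pytest.approx(14.0)
        assert res.z_focus == pytest.approx(0.0)

    def test_orientation_invariance(self):
        p = self.profile()
        rev = VarianceProfile(z=p.z[::-1].copy(), metric=p.metric[::-1].copy())
        fwd, bwd = autofocus(p), autofocus(rev)
        assert bwd.z_bright_spot == pytest.approx(fwd.z_bright_spot)
        assert bwd.z_focus == pytest.approx(fwd.z_focus)

    def test_monotone_profile_is_scan_range_error(self):
        z = np.arange(0.0, 20.0, 2.0)
        with pytest.raises(ScanRangeError):
            autofocus(VarianceProfile(z=z, metric=z * 0.1 + 1.0))

    def test_tie_breaks_toward_zero(self):
        z = np.arange(-8.0, 9.0, 2.0)
        metric = np.array([1.0, 0.2, 1.0, 1.5, 1.0, 0.2, 1.0, 3.0, 1.0])
        # minima at z=-6 and z=+2, both 8 µm from the peak at z=+6
        res = autofocus(VarianceProfile(z=z, metric=metric))
        assert res.z_bright_spot == pytest.approx(6.0)
        assert res.z_focus == pytest.approx(2.0)

    def test_phantom_stack_recovers_plane(self):
        ph = generate_slide(15, seed=21)
        zs = np.arange(-20.0, 21.0, 2.0)
        metric = [
            variance_metric(render_image(ph, None, (200.0, 200.0), z, noise=False))
            for z in zs
        ]
        res = autofocus(VarianceProfile(z=zs, metric=np.array(metric)))
        assert abs(res.z_bright_spot - 14.0) <= 2.0


class TestStitchGrid:
    def test_single_tile_identity(self, rng):
        t = tile(rng.uniform(0, 10, size=(32, 32)))
        mosaic, offsets = stitch_grid([t], nominal_overlap=0.1)
        np.testing.assert_array_equal(mosaic, t.pixels)
        np.testing.assert_array_equal(offsets, [[0.0, 0.0]])

    def test_crop_and_recover_offset(self):
        ph = generate_slide(40, seed=22)
        full = render_image(ph, None, (200.0, 200.0), ph.z_spot,
                            fov=(256, 300), pixel_size=0.5, noise=False)
        left = full.pixels[:, :160]
        right = full.pixels[:, 140:]
        px = 0.5
        # stage positions corresponding to each crop centre
        t_left = tile(left, stage_xy=(0.0, 0.0), pixel_size=px)
        x_shift = 140 * px + 0.2  # nominal off by 0.2 µm (0.4 px)
        t_right = tile(right, stage_xy=(x_shift, 0.0), pixel_size=px)
        _, offsets = stitch_grid([t_left, t_right], nominal_overlap=0.12)
        rel = offsets[1] - offsets[0]
        assert abs(rel[0] - 0.0) <= 0.5
        assert abs(rel[1] - 140.0) <= 0.5

    def test_constant_tiles_fall_back_to_nominal(self):
        a = tile(np.full((40, 40), 5.0), stage_xy=(0.0, 0.0), pixel_size=1.0)
        b = tile(np.full((40, 40), 5.0), stage_xy=(36.0, 0.0), pixel_size=1.0)
        mosaic, offsets = stitch_grid([a, b], nominal_overlap=0.1)
        np.testing.assert_allclose(offsets[1] - offsets[0], [0.0, 36.0])

    def test_non_grid_positions_rejected(self, rng):
        tiles = [
            tile(rng.uniform(size=(16, 16)), stage_xy=xy, pixel_size=1.0)
            for xy in [(0, 0), (14, 0), (7, 12)]
        ]
        with pytest.raises(ValueError):
            stitch_grid(tiles, nominal_overlap=0.1)


def gaussian_spot(shape, row, col, amp=100.0, sigma=3.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))


class TestDetectBrightSpots:
    def test_single_spot_found(self):
        img = 10.0 + gaussian_spot((64, 96), 32, 48)
        cs = detect_bright_spots(img, sigma=2.0)
        assert len(cs) == 1
        assert np.hypot(cs.points[0, 0] - 32, cs.points[0, 1] - 48) <= 1.0

    def test_constant_image_empty(self):
        assert len(detect_bright_spots(np.full((32, 32), 3.0))) == 0

    def test_grid_of_nine_spots(self):
        img = np.full((150, 150), 5.0)
        truth = [(r, c) for r in (30, 75, 120) for c in (30, 75, 120)]
        for r, c in truth:
            img += gaussian_spot(img.shape, r, c)
        cs = detect_bright_spots(img, sigma=2.0, min_distance=10)
        assert len(cs) == 9
        for r, c in truth:
            d = np.hypot(cs.points[:, 0] - r, cs.points[:, 1] - c)
            assert d.min() <= 1.0

    def test_count_monotone_in_prominence_and_distance(self, rng):
        img = np.full((120, 120), 2.0)
        for _ in range(12):
            r, c = rng.uniform(10, 110, size=2)
            img += gaussian_spot(img.shape, r, c, amp=rng.uniform(20, 120))
        counts_p = [
            len(detect_bright_spots(img, sigma=2.0, prominence=p))
            for p in (0.05, 0.2, 0.5, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts_p, counts_p[1:]))
        counts_d = [
            len(detect_bright_spots(img, sigma=2.0, min_distance=d))
            for d in (3, 8, 20, 40)
        ]
        assert all(a >= b for a, b in zip(counts_d, counts_d[1:]))


class TestSelectIsolated:
    def test_most_isolated_kept(self):
        cs = CandidateSet(points=[(0, 0), (1, 0), (100, 100)], score=[1, 1, 1])
        out = select_isolated(cs, 1)
        np.testing.assert_array_equal(out.points, [[100, 100]])

    def test_keep_all_is_identity(self, rng):
        pts = rng.uniform(0, 50, size=(10, 2))
        cs = CandidateSet(points=pts, score=np.ones(10))
        out = select_isolated(cs, 10)
        np.testing.assert_array_equal(np.sort(out.points, axis=0), np.sort(pts, axis=0))

    def test_matches_brute_force_top_k(self, rng):
        pts = rng.uniform(0, 200, size=(200, 2))
        cs = CandidateSet(points=pts, score=rng.uniform(size=200))
        kept = select_isolated(cs, 50)
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        iso = d.min(axis=1)
        kept_iso = sorted(iso[np.argsort(-iso)[:50]])
        # every kept candidate is at least as isolated as every discarded one
        got = []
        for p in kept.points:
            idx = int(np.argmin(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])))
            got.append(iso[idx])
        assert min(got) >= max(np.delete(iso, [int(np.argmin(np.hypot(pts[:,0]-p[0], pts[:,1]-p[1]))) for p in kept.points]))
        np.testing.assert_allclose(sorted(got), kept_iso)


class TestOrderRoute:
    def test_collinear_points_in_order(self):
        pts = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0), (30.0, 0.0)]
        tl = order_route(np.array(pts)[[2, 0, 3, 1]], start=(0.0, 0.0))
        np.testing.assert_array_equal(tl.stage_xy[:, 0], [0.0, 10.0, 20.0, 30.0])

    def test_single_point(self):
        tl = order_route([(5.0, 5.0)], start=(0.0, 0.0))
        np.testing.assert_array_equal(tl.stage_xy, [[5.0, 5.0]])

    def test_greedy_no_worse_than_input_order(self, rng):
        pts = rng.uniform(0, 1000, size=(100, 2))
        start = (0.0, 0.0)
        greedy = order_route(pts, start=start).travel_length(start)
        naive = TargetList(stage_xy=pts).travel_length(start)
        assert greedy <= naive

    def test_bounded_below_by_optimal_tour(self, rng):
        pts = rng.uniform(0, 100, size=(7, 2))
        start = (0.0, 0.0)
        greedy = order_route(pts, start=start).travel_length(start)
        best = min(
            TargetList(stage_xy=pts[list(perm)]).travel_length(start)
            for perm in itertools.permutations(range(7))
        )
        assert greedy >= best - 1e-9


class TestPixelToStage:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(0, 100, size=(6, 2))
        amap = fit_pixel_to_stage(pts, pts)
        np.testing.assert_allclose(amap.linear, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(amap.translation, [0, 0], atol=1e-7)
        assert amap.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_map_recovery(self, rng):
        A = np.array([[0.0, 0.1613], [-0.1613, 0.0]])  # y-flip at 0.1613 µm/px
        t = np.array([500.0, -200.0])
        pix = rng.uniform(0, 2000, size=(10, 2))
        stage = pix @ A.T + t
        amap = fit_pixel_to_stage(pix, stage)
        np.testing.assert_allclose(amap.linear, A, atol=1e-9)
        np.testing.assert_allclose(amap.translation, t, atol=1e-9)
        np.testing.assert_allclose(amap(pix), stage, atol=1e-9)

    def test_collinear_points_rejected(self):
        pix = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            fit_pixel_to_stage(pix, pix * 2.0)


class TestLaserOffset:
    def test_zero_offset_identity(self):
        tl = TargetList(stage_xy=[[10.0, 10.0]])
        out = apply_laser_offset(tl, (0.0, 0.0))
        np.testing.assert_array_equal(out.stage_xy, tl.stage_xy)

    def test_translation(self):
        tl = TargetList(stage_xy=[[10.0, 10.0]])
        out = apply_laser_offset(tl, (3.0, -2.0))
        np.testing.assert_array_equal(out.stage_xy, [[13.0, 8.0]])

    def test_round_trip(self, rng):
        tl = TargetList(stage_xy=rng.uniform(0, 100, size=(5, 2)))
        off = (1.25, -0.75)
        back = apply_laser_offset(apply_laser_offset(tl, off), (-off[0], -off[1]))
        np.testing.assert_allclose(back.stage_xy, tl.stage_xy, atol=1e-12)
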