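"""Multiscale ridge detector: scale selection, NMS, linking, diameters."""

import math

import numpy as np
import pytest

import limbusflow as lf
from limbusflow.frame import FrameImage
from limbusflow.ridge import (ScaleSpaceParams, TooSmallFrameError,
                              analytic_optimal_scale_t, compute_borders,
                              detect_ridge_points, estimate_diameter,
                              link_ridges, render_overlay,
                              scale_space_response, segment_frame)


def _ridge_frame(px_spec, sigma0, angle_deg=0.0, amplitude=100.0, offset_um=0.0):
    v = lf.VesselTruth(lf.straight_centerline(px_spec, angle_deg, offset_um),
                       sigma0, amplitude)
    return lf.generate_vessel_frame(px_spec, [v])[0]


def _midline_points(points, px_spec, row=128.0, margin=2.0, x_range=(50, 200)):
    return [p for p in points
            if abs(p.position_px[1] - row) < margin
            and x_range[0] < p.position_px[0] < x_range[1]]


class TestScaleSpaceResponse:
    def test_constant_image_zero_response(self, px_spec):
        frame = FrameImage(np.full((256, 256), 7.0), 1.0)
        stack = scale_space_response(frame, ScaleSpaceParams())
        assert np.all(stack.responses == 0.0)

    def test_closed_form_matches_dense_scan(self):
        """Independent oracle: the analytic optimum t* = gamma sigma0^2/(3/2-gamma)
        agrees with a brute-force argmax of R(t) = t^g sigma0 (sigma0^2+t)^(-3/2)
        over a dense scale grid."""
        for sigma0 in (3.0, 6.0, 9.0, 12.0):
            for gamma in (0.5, 0.75, 1.0):
                t = np.linspace(0.01, 40.0 ** 2, 400_000)
                r = t ** gamma * sigma0 * (sigma0 ** 2 + t) ** -1.5
                t_star = t[np.argmax(r)]
                assert t_star == pytest.approx(
                    analytic_optimal_scale_t(sigma0, gamma), rel=1e-3)

    @pytest.mark.parametrize("sigma0", [3.0, 6.0, 9.0, 12.0])
    @pytest.mark.parametrize("gamma,factor", [(0.75, 1.0), (1.0, math.sqrt(2.0))])
    def test_selected_scale_on_gaussian_ridge(self, px_spec, sigma0, gamma, factor):
        """On a noiseless Gaussian ridge the selected scale equals the
        analytic optimum: sigma* = sigma0 for gamma = 0.75, sigma0*sqrt(2)
        for gamma = 1."""
        frame = _ridge_frame(px_spec, sigma0)
        params = ScaleSpaceParams(gamma=gamma, response_threshold=0.5)
        points = detect_ridge_points(scale_space_response(frame, params), params)
        mid = _midline_points(points, px_spec)
        assert mid
        sigma_star = np.median([p.sigma_star_um for p in mid])
        assert sigma_star == pytest.approx(factor * sigma0, rel=0.02)

    def test_too_small_frame_raises(self):
        frame = FrameImage(np.zeros((64, 64)), 1.0)
        with pytest.raises(TooSmallFrameError):
            scale_space_response(frame, ScaleSpaceParams())

    def test_max_over_scales_equals_bruteforce(self, px_spec):
        """Per-pixel max/argmax over the stack equals an explicit loop."""
        frame = _ridge_frame(px_spec, 5.0, angle_deg=30.0)
        stack = scale_space_response(frame, ScaleSpaceParams())
        rmax = stack.responses.max(axis=0)
        idx = np.argmax(stack.responses, axis=0)
        brute_max = np.zeros_like(rmax)
        brute_idx = np.zeros_like(idx)
        for k in range(stack.responses.shape[0]):
            better = stack.responses[k] > brute_max
            brute_max[better] = stack.responses[k][better]
            brute_idx[better] = k
        assert np.array_equal(rmax, brute_max)
        assert np.array_equal(idx, brute_idx)


class TestDetectRidgePoints:
    def test_noiseless_ridge_centerline_within_half_pixel(self, px_spec):
        """Brute-force oracle: per-column argmax of the image gives the
        centerline row; detected sub-pixel midline agrees within 0.5 px."""
        frame = _ridge_frame(px_spec, 6.0)
        col_argmax = np.argmax(frame.pixels, axis=0)  # oracle, per column
        params = ScaleSpaceParams(response_threshold=1.0)
        points = detect_ridge_points(scale_space_response(frame, params), params)
        mid = _midline_points(points, px_spec)
        assert len(mid) > 100
        for p in mid:
            x = int(round(p.position_px[0]))
            assert abs(p.position_px[1] - col_argmax[x]) <= 0.5

    def test_threshold_above_max_gives_empty(self, px_spec):
        frame = _ridge_frame(px_spec, 6.0)
        params = ScaleSpaceParams(response_threshold=1e9)
        assert detect_ridge_points(scale_space_response(frame, params), params) == []

    def test_two_parallel_ridges_resolved(self, px_spec):
        """Two ridges 60 um apart (sigma0 = 6 um): two point sets, none
        in the valley between them."""
        v1 = lf.VesselTruth(lf.straight_centerline(px_spec, 0.0, -30.0), 6.0, 100.0)
        v2 = lf.VesselTruth(lf.straight_centerline(px_spec, 0.0, +30.0), 6.0, 100.0)
        frame, _ = lf.generate_vessel_frame(px_spec, [v1, v2])
        params = ScaleSpaceParams(response_threshold=1.0)
        points = detect_ridge_points(scale_space_response(frame, params), params)
        rows = np.array([p.position_px[1] for p in points
                         if 50 < p.position_px[0] < 200])
        assert np.any(np.abs(rows - 98.0) < 2) and np.any(np.abs(rows - 158.0) < 2)
        assert not np.any(np.abs(rows - 128.0) < 10)


class TestLinking:
    def test_single_ridge_links_to_one_segment(self, px_spec):
        frame = _ridge_frame(px_spec, 6.0, angle_deg=15.0)
        params = ScaleSpaceParams(response_threshold=1.0)
        points = detect_ridge_points(scale_space_response(frame, params), params)
        segments = link_ridges(points, params)
        assert len(segments) == 1
        assert len(segments[0].points) >= 0.9 * len(points)

    def test_empty_input_empty_output(self):
        assert link_ridges([], ScaleSpaceParams()) == []

    def test_crossing_ridges_split_by_orientation(self, px_spec):
        """X phantom (arms 60 deg apart): orientation-gated linking yields 2
        segments and assigns the crossing to exactly one of them."""
        v1 = lf.VesselTruth(lf.straight_centerline(px_spec, +30.0), 5.0, 100.0)
        v2 = lf.VesselTruth(lf.straight_centerline(px_spec, -30.0), 5.0, 100.0)
        frame, _ = lf.generate_vessel_frame(px_spec, [v1, v2])
        params = ScaleSpaceParams(response_threshold=1.0, min_segment_len_px=20)
        points = detect_ridge_points(scale_space_response(frame, params), params)
        segments = link_ridges(points, params)
        big = [s for s in segments if len(s.points) >= 50]
        assert len(big) == 2
        # the point nearest the crossing belongs to exactly one segment
        center = np.array([128.0, 128.0])
        all_pts = [(p, s) for s in segments for p in s.points]
        nearest_p, _ = min(all_pts,
                           key=lambda ps: np.hypot(*(np.array(ps[0].position_px) - center)))
        assert sum(nearest_p in s.points for s in segments) == 1
        # and no point belongs to two segments
        ids = [id(p) for s in segments for p in s.points]
        assert len(ids) == len(set(ids))


class TestDiameter:
    def test_degenerate_width_near_zero(self):
        p = lf.RidgePoint((0.0, 0.0), 0.0, lf.PSF_SIGMA_UM, 1.0)
        seg = lf.VesselSegment([p])
        d = estimate_diameter(seg)
        assert d[0] == pytest.approx(lf.FWHM_PER_SIGMA * math.sqrt(1e-4), rel=1e-6)

    def test_amplitude_invariance(self, px_spec):
        """Doubling all intensities leaves diameters unchanged (the Hessian
        is homogeneous in intensity; scale selection is an argmax)."""
        frame = _ridge_frame(px_spec, 6.0, amplitude=50.0)
        doubled = FrameImage(frame.pixels * 2.0, frame.pitch_um)
        params = ScaleSpaceParams(response_threshold=0.2)
        d1 = segment_frame(frame, params, psf_sigma_um=0.0)[0].diameters_um
        d2 = segment_frame(doubled, params, psf_sigma_um=0.0)[0].diameters_um
        assert np.allclose(np.sort(d1), np.sort(d2))

    def test_monotone_in_true_fwhm(self):
        """Median estimated diameter strictly increases with true FWHM."""
        spec = lf.FrameSpec(grid_px=256, background_au=0.0, noise_sd_au=0.0)
        medians = []
        for fwhm in (10.0, 20.0, 30.0, 40.0, 50.0):
            v = lf.VesselTruth.from_fwhm(lf.straight_centerline(spec), fwhm, 100.0)
            frame, _ = lf.generate_vessel_frame(spec, [v])
            segs = segment_frame(frame, ScaleSpaceParams(response_threshold=1.0))
            medians.append(max(segs, key=lambda s: len(s.points)).median_diameter_um)
        assert np.all(np.diff(medians) > 0)

    def test_rotation_invariance(self):
        """Diameter of the same phantom rotated 0-170 deg varies < 5% rel SD."""
        spec = lf.FrameSpec(grid_px=256, background_au=0.0, noise_sd_au=0.0)
        medians = []
        for ang in range(0, 180, 10):
            v = lf.VesselTruth.from_fwhm(
                lf.straight_centerline(spec, angle_deg=float(ang)), 30.0, 100.0)
            frame, _ = lf.generate_vessel_frame(spec, [v])
            segs = segment_frame(frame, ScaleSpaceParams(response_threshold=1.0))
            medians.append(max(segs, key=lambda s: len(s.points)).median_diameter_um)
        medians = np.array(medians)
        assert medians.std() / medians.mean() < 0.05

    def test_translation_equivariance(self, px_spec):
        """Whole-pixel phantom shifts shift the detected midline identically."""
        params = ScaleSpaceParams(response_threshold=1.0)
        f0 = _ridge_frame(px_spec, 6.0, offset_um=0.0)
        f1 = _ridge_frame(px_spec, 6.0, offset_um=7.0)  # 7 px at 1 um pitch
        def midrow(frame):
            pts = detect_ridge_points(scale_space_response(frame, params), params)
            return np.median([p.position_px[1] for p in
                              _midline_points(pts, px_spec, row=135.0, margin=10.0)])
        assert midrow(f1) - midrow(f0) == pytest.approx(7.0, abs=0.5)

    def test_scale_clipped_points_flagged(self, px_spec):
        """sigma* at the boundary of the scale grid is kept but flagged."""
        frame = _ridge_frame(px_spec, 1.2)  # below the 1.5 um grid floor
        params = ScaleSpaceParams(response_threshold=1.0)
        pts = detect_ridge_points(scale_space_response(frame, params), params)
        mid = _midline_points(pts, px_spec)
        assert mid and all(p.scale_clipped for p in mid)


class TestOverlay:
    def test_no_segments_grayscale_only(self, px_spec):
        frame = _ridge_frame(px_spec, 6.0)
        rgb = render_overlay(frame, [])
        assert rgb.dtype == np.uint8 and rgb.shape == (256, 256, 3)
        assert np.array_equal(rgb[..., 0], rgb[..., 1])
        assert np.array_equal(rgb[..., 1], rgb[..., 2])

    def test_red_pixel_count_matches_midline(self, px_spec):
        frame = _ridge_frame(px_spec, 6.0)
        segs = segment_frame(frame, ScaleSpaceParams(response_threshold=1.0))
        rgb = render_overlay(frame, segs)
        red = np.all(rgb == (255, 0, 0), axis=-1)
        expected = {tuple(np.round(p.position_px).astype(int))
                    for s in segs for p in s.points}
        expected = {xy for xy in expected if 0 <= xy[0] < 256 and 0 <= xy[1] < 256}
        assert red.sum() == len(expected)

    def test_border_offset_matches_radius(self, px_spec):
        frame = _ridge_frame(px_spec, 6.0)
        segs = segment_frame(frame, ScaleSpaceParams(response_threshold=1.0),
                             psf_sigma_um=0.0)
        seg = max(segs, key=lambda s: len(s.points))
        compute_borders(seg, frame.pitch_um)
        rgb = render_overlay(frame, [seg])
        red_yx = np.argwhere(np.all(rgb == (255, 0, 0), axis=-1))
        blue_yx = np.argwhere(np.all(rgb == (0, 0, 255), axis=-1))
        dists = [np.min(np.hypot(*(red_yx - b).T)) for b in blue_yx]
        median_radius_px = seg.median_diameter_um / 2.0 / frame.pitch_um
        assert np.mean(dists) == pytest.approx(median_radius_px, abs=1.0)
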