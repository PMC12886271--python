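"""Tests for droplet micrograph quantification."""

import numpy as np
import pytest

from dropstress.imaging import (
    ImageFrame,
    fit_ellipse,
    functionalization_signal,
    preprocess_frames,
    segment_inner_droplets,
    select_equatorial_plane,
    surface_weighted_cdf,
    track_droplet_stress,
)
from dropstress.mechanics import EllipseFit, MechanicalContext
from dropstress.synthetic import (
    EmulsionFieldSpec,
    StressedDropletSpec,
    make_emulsion_field,
    make_stressed_droplet,
    _render_disk,
)


def ellipse_points(cx, cy, a, b, theta, n=100, rng=None, noise=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    x = cx + b * ct * np.cos(t) - a * st * np.sin(t)
    y = cy + b * st * np.cos(t) + a * ct * np.sin(t)
    pts = np.column_stack([x, y])
    if noise:
        pts += rng.normal(0, noise, pts.shape)
    return pts


class TestPreprocess:
    def test_single_clean_frame_unchanged(self):
        px = np.full((64, 64), 50.0)
        px[10:20, 10:20] = 200.0  # below 10x background
        frame = ImageFrame(px, 0.1)
        (out,) = preprocess_frames([frame])
        assert np.array_equal(out.pixels, px)

    def test_identical_frames_idempotent(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(10, 60, (64, 64))
        frames = [ImageFrame(px, 0.1), ImageFrame(px.copy(), 0.1)]
        out = preprocess_frames(frames)
        assert np.allclose(out[1].pixels, out[0].pixels)

    def test_hot_pixel_capped_at_ten_times_background(self):
        px = np.full((64, 64), 50.0)
        px[32, 32] = 5000.0  # 100x background
        (out,) = preprocess_frames([ImageFrame(px, 0.1)])
        bg = np.median(px)  # single hot pixel leaves the median at 50
        assert out.pixels[32, 32] == pytest.approx(10.0 * bg)

    def test_shape_mismatch_rejected(self):
        a = ImageFrame(np.zeros((8, 8)), 0.1)
        b = ImageFrame(np.zeros((8, 9)), 0.1)
        with pytest.raises(ValueError):
            preprocess_frames([a, b])


class TestSegmentation:
    def test_blank_frame_empty_distribution(self):
        frame = ImageFrame(np.full((64, 64), 7.0), 0.1)
        dist = segment_inner_droplets(frame)
        assert len(dist) == 0

    def test_known_disks_recovered(self):
        """Non-touching disks of known diameters are each found within 1 px."""
        rng = np.random.default_rng(3)
        img = np.zeros((600, 600))
        truth = []
        for _ in range(50):
            for _attempt in range(200):
                d_um = rng.uniform(0.5, 1.6)
                r_px = d_um / 2 / 0.1
                cx, cy = rng.uniform(20, 580, 2)
                if all(np.hypot(cx - x, cy - y) > r_px + rr + 4 for x, y, rr in truth):
                    break
            _render_disk(img, cx, cy, r_px, 900.0)
            truth.append((cx, cy, r_px))
        frame = ImageFrame(img + 100.0, 0.1)
        dist = segment_inner_droplets(frame, threshold=550.0)
        assert len(dist) == 50
        meas = np.sort(dist.diameters)
        want = np.sort([2 * r * 0.1 for _, _, r in truth])
        assert np.all(np.abs(meas - want) < 0.1)  # 1 px = 0.1 um

    def test_watershed_splits_touching_disks(self):
        img = np.zeros((80, 80))
        r = 8.0
        _render_disk(img, 30.0, 40.0, r, 900.0)
        _render_disk(img, 30.0 + 1.8 * r, 40.0, r, 900.0)  # overlap ~20% of r
        frame = ImageFrame(img + 100.0, 0.1)
        dist = segment_inner_droplets(frame, threshold=550.0)
        assert len(dist) == 2

    def test_area_and_circularity_filters(self):
        img = np.zeros((120, 120))
        _render_disk(img, 30.0, 30.0, 5.0, 900.0)  # kept
        img[60, 60] = 900.0  # 1-2 px speck: area filter
        img[90:92, 10:70] = 900.0  # long thin bar: circularity filter
        frame = ImageFrame(img + 100.0, 0.1)
        dist = segment_inner_droplets(frame, threshold=550.0)
        assert len(dist) == 1
        assert np.all(dist.areas >= 6 * 0.1**2)
        assert np.all(dist.circularities >= 0.5)

    def test_resolution_floor_applied_after_filters(self):
        """Flooring rewrites small diameters but never drops objects."""
        img = np.zeros((60, 60))
        img[30:32, 30:33] = 900.0  # 6 px^2 block: kept, d = 0.276 um < floor
        frame = ImageFrame(img + 100.0, 0.1)
        dist = segment_inner_droplets(frame, threshold=550.0)
        assert len(dist) == 1
        assert dist.diameters[0] == pytest.approx(0.3)

    def test_lognormal_mean_recovered_on_large_field(self):
        spec = EmulsionFieldSpec(
            n_droplets=500, field_size=(1600, 1600), pixel_size=0.1, seed=2
        )
        frame, truth = make_emulsion_field(spec)
        dist = segment_inner_droplets(frame, threshold=550.0)
        assert len(dist) >= 0.95 * spec.n_droplets
        assert dist.mean_diameter == pytest.approx(
            spec.diameter_law[0], rel=0.05
        )


class TestSurfaceWeightedCDF:
    def test_monodisperse_step(self):
        d, cdf = surface_weighted_cdf(np.full(10, 0.8))
        assert np.all(d == 0.8)
        assert cdf[-1] == 1.0

    def test_two_droplet_weights(self):
        d, cdf = surface_weighted_cdf(np.array([1.0, 2.0]))
        assert cdf[0] == pytest.approx(1.0 / 5.0)  # d^2 weights 1:4
        assert cdf[-1] == 1.0

    def test_coincides_with_number_cdf_iff_monodisperse(self):
        mono_d, mono = surface_weighted_cdf(np.full(5, 1.0))
        assert np.allclose(mono, np.arange(1, 6) / 5.0)
        d, surf = surface_weighted_cdf(np.array([1.0, 1.0, 3.0]))
        number = np.arange(1, 4) / 3.0
        assert not np.allclose(surf, number)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            surface_weighted_cdf(np.array([]))


class TestFunctionalizationSignal:
    def test_uniform_image_gives_exactly_one(self):
        frame = ImageFrame(np.full((128, 128), 37.0), 0.5)
        fit = EllipseFit(a=30.0, b=30.0, center_xy=(63.5, 63.5), pixel_size=0.5)
        assert functionalization_signal(frame, fit, ring_width=3.0).signal == 1.0

    def test_ring_fixture_returns_contrast(self):
        ctx = MechanicalContext(E=1000.0, gamma=0.0, R=30e-6, sigma_inf=0.0)
        spec = StressedDropletSpec(context=ctx, ring_contrast=3.0)
        frame, truth = make_stressed_droplet(spec)
        meas = functionalization_signal(
            frame, truth, ring_width=spec.ring_width_px * spec.pixel_size
        )
        assert meas.signal == pytest.approx(3.0, rel=0.08)

    def test_invariant_under_intensity_scaling(self):
        ctx = MechanicalContext(E=1000.0, gamma=0.0, R=30e-6, sigma_inf=0.0)
        spec = StressedDropletSpec(context=ctx, ring_contrast=2.0)
        frame, truth = make_stressed_droplet(spec)
        s1 = functionalization_signal(frame, truth, ring_width=3.0).signal
        scaled = ImageFrame(frame.pixels * 11.0, frame.pixel_size)
        s2 = functionalization_signal(scaled, truth, ring_width=3.0).signal
        assert s2 == pytest.approx(s1, rel=1e-12)

    def test_contour_touching_edge_rejected(self):
        frame = ImageFrame(np.full((64, 64), 10.0), 0.5)
        fit = EllipseFit(a=40.0, b=40.0, center_xy=(31.5, 31.5), pixel_size=0.5)
        with pytest.raises(ValueError, match="edge"):
            functionalization_signal(frame, fit, ring_width=3.0)

    def test_droplet_smaller_than_ring_rejected(self):
        frame = ImageFrame(np.full((64, 64), 10.0), 0.5)
        fit = EllipseFit(a=4.0, b=4.0, center_xy=(31.5, 31.5), pixel_size=0.5)
        with pytest.raises(ValueError, match="ring"):
            functionalization_signal(frame, fit, ring_width=3.0)


class TestEllipseFit:
    def test_circle(self):
        pts = ellipse_points(100, 100, 50, 50, 0.0)
        fit = fit_ellipse(pts)
        assert fit.a == pytest.approx(50.0, abs=1e-6)
        assert fit.b == pytest.approx(50.0, abs=1e-6)

    def test_noiseless_round_trip(self):
        pts = ellipse_points(120, 80, 40, 60, np.pi / 6)
        fit = fit_ellipse(pts)
        assert fit.a == pytest.approx(40.0, rel=1e-6)
        assert fit.b == pytest.approx(60.0, rel=1e-6)
        assert fit.orientation == pytest.approx(np.pi / 6, abs=1e-6)
        assert fit.center_xy[0] == pytest.approx(120.0, abs=1e-6)

    def test_noisy_monte_carlo_axis_error(self):
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(50):
            pts = ellipse_points(120, 80, 40, 60, 0.4, rng=rng, noise=1.0)
            fit = fit_ellipse(pts)
            errs.append(max(abs(fit.a - 40.0), abs(fit.b - 60.0)))
        assert np.median(errs) < 0.5  # px

    def test_rotation_translation_equivariance(self):
        pts = ellipse_points(0, 0, 40, 60, 0.0)
        fit0 = fit_ellipse(pts)
        angle, shift = 0.7, np.array([55.0, -20.0])
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        fit1 = fit_ellipse(pts @ rot.T + shift)
        assert fit1.a == pytest.approx(fit0.a, rel=1e-8)
        assert fit1.b == pytest.approx(fit0.b, rel=1e-8)
        assert fit1.orientation == pytest.approx(
            (fit0.orientation + angle) % np.pi, abs=1e-6
        )

    def test_degenerate_points_rejected(self):
        line = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            fit_ellipse(line)
        with pytest.raises(ValueError):
            fit_ellipse(line[:4])


class TestStressTracking:
    def test_circular_frames_zero_stress(self):
        frames = [ImageFrame(np.zeros((32, 32)), 1e-6) for _ in range(3)]
        contours = [ellipse_points(16, 16, 10, 10, 0.0) for _ in range(3)]
        series = track_droplet_stress(frames, contours, gamma=4e-3)
        assert all(abs(s.value) < 1e-6 for s in series)

    def test_ramping_deformation_monotonic_stress(self):
        frames, contours = [], []
        for ratio in np.linspace(1.0, 1.2, 6):
            frames.append(ImageFrame(np.zeros((64, 64)), 1e-6))
            a = 15.0 / np.sqrt(ratio)
            contours.append(ellipse_points(32, 32, a, a * ratio, 0.0))
        series = track_droplet_stress(frames, contours, gamma=4e-3)
        values = [s.value for s in series]
        assert np.all(np.diff(values) > 0)

    def test_uncertainty_shrinks_with_finer_pixels(self):
        contour = ellipse_points(32, 32, 12, 16, 0.0)
        coarse = track_droplet_stress(
            [ImageFrame(np.zeros((64, 64)), 1e-6)], [contour], gamma=4e-3
        )[0]
        fine = track_droplet_stress(
            [ImageFrame(np.zeros((64, 64)), 0.5e-6)], [2 * contour], gamma=4e-3
        )[0]
        assert fine.uncertainty < coarse.uncertainty

    def test_equatorial_plane_is_largest_section(self):
        frames, contours = [], []
        for r in [10.0, 14.0, 12.0]:
            frames.append(ImageFrame(np.zeros((64, 64)), 1e-6))
            contours.append(ellipse_points(32, 32, r, r, 0.0))
        assert select_equatorial_plane(frames, contours) == 1
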