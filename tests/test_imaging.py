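"""Diameter extraction: registration, caliper measurement, line scans."""

import numpy as np
import pytest

from vasoreact.imaging import (
    Caliper,
    ImageStack,
    LineScan,
    linescan_diameter,
    measure_diameter,
    measure_wall_thickness,
    register_stack,
)
from vasoreact.synthetic import (
    ResponseKinetics,
    StimulusProtocol,
    VesselScene,
    generate_diameter_trace,
    render_image_stack,
    render_linescan,
)
from vasoreact.traces import DiameterTrace


def _flat_trace(diam_um, n_frames=4, dt=50.0):
    time = np.arange(n_frames) * dt
    end = time[-1] + dt
    return DiameterTrace(time, np.full(n_frames, diam_um), (0.0, end), end, 0.0)


def _centered_caliper(stack, angle=0.0):
    ny, nx = stack.frames.shape[1:]
    return Caliper((nx / 2, ny / 2), angle, nx - 2)


class TestRegistration:
    def test_identical_frames_give_zero_shifts(self, scene):
        stack, _ = render_image_stack(_flat_trace(20.0), scene, seed=0)
        _, shifts = register_stack(stack)
        assert np.allclose(shifts, 0.0, atol=0.05)

    def test_known_drift_recovered(self, scene):
        tr = _flat_trace(20.0, n_frames=6)
        drift = np.zeros((6, 2))
        drift[3:] = (3.0, -2.0)
        stack, _ = render_image_stack(tr, scene, seed=0, drift=drift)
        _, shifts = register_stack(stack)
        assert np.allclose(shifts[3:], (3.0, -2.0), atol=0.5)
        assert np.allclose(shifts[:3], 0.0, atol=0.5)

    def test_pure_noise_frames_clamped_with_warning(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.normal(size=(3, 64, 64)), 0.5, 1.0)
        with pytest.warns(UserWarning, match="max_shift"):
            _, shifts = register_stack(stack, max_shift=2.0)
        assert np.all(np.hypot(shifts[:, 0], shifts[:, 1]) <= 2.0 + 1e-9)

    def test_registration_then_measurement_matches_drift_free(self, scene):
        tr = _flat_trace(24.0, n_frames=6)
        drift = np.zeros((6, 2))
        drift[2:] = (4.0, 1.0)
        clean, _ = render_image_stack(tr, scene, seed=1)
        drifted, _ = render_image_stack(tr, scene, seed=1, drift=drift)
        registered, _ = register_stack(drifted)
        cal = _centered_caliper(clean)
        d_clean = measure_diameter(clean, cal).diameter
        d_reg = measure_diameter(registered, cal).diameter
        assert np.nanmax(np.abs(d_clean - d_reg)) / scene.pixel_size < 0.5

    def test_empty_reference_rejected(self, scene):
        stack, _ = render_image_stack(_flat_trace(20.0), scene, seed=0)
        with pytest.raises(IndexError):
            register_stack(stack, reference_index=99)


class TestMeasureDiameter:
    @pytest.mark.parametrize("diam_px", [20, 30, 60])
    def test_noiseless_width_within_half_pixel(self, scene, diam_px):
        tr = _flat_trace(diam_px * scene.pixel_size, n_frames=2)
        stack, truth = render_image_stack(tr, scene, seed=0)
        got = measure_diameter(stack, _centered_caliper(stack))
        assert np.nanmax(np.abs(got.diameter / scene.pixel_size - truth)) < 0.5

    def test_affine_intensity_invariance(self, scene):
        tr = _flat_trace(25.0, n_frames=2)
        stack, _ = render_image_stack(tr, scene, seed=0)
        cal = _centered_caliper(stack)
        base = measure_diameter(stack, cal).diameter
        rescaled = ImageStack(stack.frames * 2.0 + 0.3, stack.pixel_size, stack.frame_interval)
        assert np.allclose(measure_diameter(rescaled, cal).diameter, base, atol=1e-9)

    def test_constriction_ramp_tracked(self, scene):
        # 30 px → 24 px linear ramp across frames
        n = 7
        diam_um = np.linspace(30, 24, n) * scene.pixel_size
        time = np.arange(n) * 50.0
        tr = DiameterTrace(time, diam_um, (0.0, time[-1]), time[-1] + 50.0, 0.0)
        stack, truth = render_image_stack(tr, scene, seed=0)
        got = measure_diameter(stack, _centered_caliper(stack)).diameter / scene.pixel_size
        assert np.all(np.diff(got) < 0)
        assert np.nanmax(np.abs(got - truth)) < 0.5

    def test_unresolvable_walls_marked_missing(self, scene):
        stack, _ = render_image_stack(_flat_trace(20.0, n_frames=2), scene, seed=0)
        flat = ImageStack(np.full_like(stack.frames, 0.5), stack.pixel_size, stack.frame_interval)
        got = measure_diameter(flat, _centered_caliper(flat))
        assert np.all(np.isnan(got.diameter))
        assert not got.valid.any()

    def test_oblique_vessel_measured_along_perpendicular_caliper(self):
        scene = VesselScene(noise_sd=0.0, orientation=20.0)
        stack, truth = render_image_stack(_flat_trace(22.0, n_frames=2), scene, seed=0)
        got = measure_diameter(stack, _centered_caliper(stack, angle=-20.0))
        assert np.nanmax(np.abs(got.diameter / scene.pixel_size - truth)) < 0.5

    def test_trough_method_exceeds_half_depth_width(self, scene):
        # trough-to-trough spans the walls and must be wider than the lumen
        stack, _ = render_image_stack(_flat_trace(20.0, n_frames=1), scene, seed=0)
        cal = _centered_caliper(stack)
        hd = measure_diameter(stack, cal, method="half_depth").diameter[0]
        tt = measure_diameter(stack, cal, method="trough").diameter[0]
        assert tt > hd


class TestWallThickness:
    def test_four_micron_wall_recovered(self, scene):
        stack, _ = render_image_stack(_flat_trace(20.0), scene, seed=0)
        w = measure_wall_thickness(stack, _centered_caliper(stack))
        assert w == pytest.approx(scene.wall_thickness, abs=scene.pixel_size / 2)

    def test_micron_result_independent_of_pixel_size(self):
        for px in (0.5, 1.0):
            sc = VesselScene(noise_sd=0.0, pixel_size=px)
            stack, _ = render_image_stack(_flat_trace(20.0), sc, seed=0)
            w = measure_wall_thickness(stack, _centered_caliper(stack))
            assert w == pytest.approx(sc.wall_thickness, abs=px / 2)

    def test_unresolvable_walls_return_nan(self, scene):
        stack, _ = render_image_stack(_flat_trace(20.0), scene, seed=0)
        flat = ImageStack(np.full_like(stack.frames, 0.5), stack.pixel_size, stack.frame_interval)
        assert np.isnan(measure_wall_thickness(flat, _centered_caliper(flat)))


class TestLineScan:
    def test_noiseless_fwhm_within_half_pixel(self, scene):
        tr = _flat_trace(20 * scene.pixel_size, n_frames=4, dt=1.0)
        ls, truth = render_linescan(tr, scene, line_rate=100, seed=0)
        got = linescan_diameter(ls, 0.1)
        assert np.nanmax(np.abs(got.diameter / scene.pixel_size - 20)) < 0.5

    def test_averaging_identical_trials_is_idempotent(self, scene):
        tr = _flat_trace(20.0, n_frames=4, dt=1.0)
        ls, _ = render_linescan(tr, scene, line_rate=100, seed=0)
        doubled = LineScan(
            np.repeat(ls.lines, 2, axis=0), ls.line_interval / 2, ls.pixel_size
        )
        a = linescan_diameter(ls, 0.1).diameter
        b = linescan_diameter(doubled, 0.1).diameter
        assert np.allclose(a, b, atol=1e-9)

    def test_step_constriction_appears_in_correct_bin(self, scene):
        time = np.array([0.0, 2.0, 2.01, 4.0])
        diam = np.array([30.0, 30.0, 24.0, 24.0]) * scene.pixel_size
        tr = DiameterTrace(time, diam, (0.0, 4.0), 5.0, 0.0)
        ls, _ = render_linescan(tr, scene, line_rate=200, seed=0)
        got = linescan_diameter(ls, 0.1)
        px = got.diameter / scene.pixel_size
        assert np.all(np.abs(px[got.time < 1.9] - 30) < 0.5)
        assert np.all(np.abs(px[got.time > 2.2] - 24) < 0.5)

    def test_bin_must_cover_line_interval(self, scene):
        tr = _flat_trace(20.0, n_frames=2, dt=1.0)
        ls, _ = render_linescan(tr, scene, line_rate=5, seed=0)
        with pytest.raises(ValueError):
            linescan_diameter(ls, 0.1)

    def test_contrast_invariance(self, scene):
        tr = _flat_trace(20.0, n_frames=2, dt=1.0)
        ls, _ = render_linescan(tr, scene, line_rate=50, seed=0)
        scaled = LineScan(ls.lines * 3.0, ls.line_interval, ls.pixel_size)
        assert np.allclose(
            linescan_diameter(ls, 0.1).diameter,
            linescan_diameter(scaled, 0.1).diameter,
            atol=1e-9,
        )


class TestNoiseRobustness:
    def test_five_percent_noise_within_one_pixel_most_frames(self):
        scene = VesselScene(noise_sd=0.05)
        tr = _flat_trace(25.0, n_frames=20)
        stack, truth = render_image_stack(tr, scene, seed=7)
        got = measure_diameter(stack, _centered_caliper(stack))
        err = np.abs(got.diameter / scene.pixel_size - truth)
        assert np.mean(err[np.isfinite(err)] <= 1.0) >= 0.95
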