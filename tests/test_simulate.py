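"""Forward simulator: plume physics, rendering, noise determinism."""

import numpy as np
import pytest

from plifscan import (
    CameraNoiseModel,
    OpticalProperties,
    PlumeScene,
    SystemConfig,
    build_map,
    concentration_field,
    render_background,
    render_frame,
    simulate_scan,
)
from plifscan.simulate import field_on_grid


class TestConcentrationField:
    def test_zero_before_emission(self):
        scene = PlumeScene()
        pts = np.array([[250.0, 100.0, 250.0]])
        assert concentration_field(scene, 0.0, pts)[0] == 0.0

    def test_points_outside_chamber_rejected(self):
        with pytest.raises(ValueError, match="chamber"):
            concentration_field(PlumeScene(), 1.0, [[600.0, 0.0, 0.0]])

    def test_mass_conservation(self):
        # emit for 2 s, observe at 6 s: every puff is wide enough for the
        # integration grid to resolve, and walls confine the tracer
        scene = PlumeScene(source_duration_s=2.0, diffusion_mm2_s=150.0,
                           rise_velocity_mm_s=5.0)
        xs = np.linspace(0.0, 500.0, 81)
        ys = np.linspace(0.0, 500.0, 81)
        zs = np.linspace(0.0, 1000.0, 161)
        f = field_on_grid(scene, 6.0, xs, ys, zs)
        mass = np.trapezoid(np.trapezoid(np.trapezoid(f, zs, axis=2), ys, axis=1), xs)
        assert mass == pytest.approx(scene.emission_rate * 2.0, rel=0.01)

    def test_plume_rises_with_updraft(self):
        scene = PlumeScene(rise_velocity_mm_s=20.0, source_duration_s=60.0)
        xs = np.linspace(0, 500, 41)
        ys = np.linspace(0, 500, 41)
        zs = np.linspace(0, 1000, 81)
        cents = []
        for t in (5.0, 15.0, 30.0):
            f = field_on_grid(scene, t, xs, ys, zs)
            cents.append((f.sum(axis=(0, 2)) * ys).sum() / f.sum(axis=(0, 2)).sum())
        assert cents[0] < cents[1] < cents[2]

    def test_grid_and_point_paths_agree(self, rng):
        scene = PlumeScene(source_duration_s=5.0)
        xs = np.linspace(100, 400, 4)
        ys = np.linspace(50, 300, 3)
        zs = np.linspace(100, 400, 5)
        grid = field_on_grid(scene, 8.0, xs, ys, zs)
        pts = np.array([[x, y, z] for x in xs for y in ys for z in zs])
        flat = concentration_field(scene, 8.0, pts).reshape(4, 3, 5)
        assert np.allclose(grid, flat, rtol=1e-10)


class TestRenderFrame:
    def test_empty_scene_gives_background_offset(self):
        cfg = SystemConfig(sensor_pixels=32, bin_factor=1)
        scene = PlumeScene(emission_rate=0.0)
        noise = CameraNoiseModel(background_offset=100.0, read_noise_sigma=0.0, seed=1)
        frame = render_frame(scene, 1.0, 50.0, cfg, noise=noise)
        assert np.all(frame.intensities == 100.0)

    def test_uniform_scene_proportional_to_correction_map(self):
        cfg = SystemConfig(sensor_pixels=64, bin_factor=1)
        scene = PlumeScene(emission_rate=0.0, uniform_concentration=2.0,
                           chamber_dims_mm=cfg.chamber_dims_mm)
        frame = render_frame(scene, 1.0, 50.0, cfg, gain=500.0)
        cmap = build_map(cfg)
        assert np.allclose(frame.intensities, 1000.0 * cmap.ratios, rtol=1e-12)

    def test_same_seed_bit_identical(self):
        cfg = SystemConfig(sensor_pixels=32, bin_factor=1)
        scene = PlumeScene(source_duration_s=10.0)
        noise = CameraNoiseModel(seed=42, read_noise_sigma=3.0)
        a = render_frame(scene, 5.0, 100.0, cfg, noise=noise, gain=1e8, frame_key=3)
        b = render_frame(scene, 5.0, 100.0, cfg, noise=noise, gain=1e8, frame_key=3)
        c = render_frame(scene, 5.0, 100.0, cfg, noise=noise, gain=1e8, frame_key=4)
        assert np.array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_noise_frames_are_integer_counts(self):
        cfg = SystemConfig(sensor_pixels=32, bin_factor=1)
        noise = CameraNoiseModel(seed=0, read_noise_sigma=2.0)
        frame = render_frame(PlumeScene(), 5.0, 100.0, cfg, noise=noise, gain=1e8)
        v = frame.intensities
        assert np.all(v == np.rint(v)) and v.min() >= 0 and v.max() <= 65535

    def test_worst_case_attenuation_stays_above_95_percent(self):
        # uniform 0.5 mg/L everywhere with optics anchored so that the
        # longest path attenuates 2.87% at 0.3 mg/L: rendered intensity never
        # drops more than 5% below the unattenuated render
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        scene = PlumeScene(emission_rate=0.0, uniform_concentration=0.5,
                           chamber_dims_mm=cfg.chamber_dims_mm)
        m_max = 420.0 * 15 / 16
        l_ex = np.sqrt((cfg.r0_mm + m_max) ** 2 + m_max**2)
        optics = OpticalProperties.from_attenuation_anchor(
            2.87, 0.3, l_ex, cfg.imaging_distance_mm)
        ideal = render_frame(scene, 1.0, 250.0, cfg, gain=1000.0)
        att = render_frame(scene, 1.0, 250.0, cfg, gain=1000.0, attenuation=optics)
        ratio = att.intensities / ideal.intensities
        assert ratio.min() > 0.95
        assert np.all(ratio <= 1.0 + 1e-12)

    def test_out_of_chamber_sheet_rejected(self):
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        with pytest.raises(ValueError, match="chamber"):
            render_frame(PlumeScene(), 1.0, 5000.0, cfg)


class TestSimulateScan:
    def test_thirty_second_scan_arithmetic(self, full_track):
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        scene = PlumeScene(emission_rate=0.0, uniform_concentration=1.0)
        seq, gts = simulate_scan(scene, full_track, 30.0, cfg, gain=10.0)
        assert len(seq) == 360
        assert len(gts) == 6

    def test_static_scene_windows_identical(self, full_track):
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        scene = PlumeScene(source_duration_s=20.0)
        _, gts = simulate_scan(scene, full_track, 10.0, cfg, gain=1.0,
                               freeze_time=True)
        assert len(gts) == 2
        # the reverse sweep's grid is offset by whole voxels in z; align the
        # overlapping slabs before comparing the static field
        a, b = gts
        dz = a.spacing_mm[2]
        shift = round((b.origin_mm[2] - a.origin_mm[2]) / dz)
        nz = min(a.values.shape[2] - shift, b.values.shape[2])
        assert np.allclose(a.values[:, :, shift:shift + nz], b.values[:, :, :nz])

    def test_full_scan_determinism(self, full_track):
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        scene = PlumeScene(source_duration_s=20.0)
        noise = CameraNoiseModel(seed=9, read_noise_sigma=2.0)
        a, _ = simulate_scan(scene, full_track, 2.0, cfg, noise=noise, gain=1e8)
        b, _ = simulate_scan(scene, full_track, 2.0, cfg, noise=noise, gain=1e8)
        assert np.array_equal(a.frames, b.frames)

    def test_background_stack_has_no_signal(self):
        cfg = SystemConfig(sensor_pixels=16, bin_factor=1)
        noise = CameraNoiseModel(background_offset=50.0, read_noise_sigma=1.0, seed=3)
        frames = render_background(cfg, noise, n_frames=5)
        stack = np.stack([f.intensities for f in frames])
        assert stack.mean() == pytest.approx(50.0, abs=1.0)
        assert not np.array_equal(stack[0], stack[1])  # independent noise
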