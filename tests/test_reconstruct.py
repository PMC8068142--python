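"""Windowing, sheet placement, voxel assembly, and sweep merging."""

import numpy as np
import pytest

from plifscan import (
    BackgroundModel,
    FrameSequence,
    PlatformTrajectory,
    RawFrame,
    SystemConfig,
    VoxelVolume,
    process_frames,
    reconstruct_volume,
    simulate_scan,
    sweep_direction_merge,
    window_frames,
)
from plifscan.reconstruct import place_frame
from plifscan.simulate import PlumeScene


def _sequence(n, side=8, rate=12.0, value=1.0):
    frames = np.full((n, side, side), value)
    t = np.arange(n) / rate
    p = np.arange(n) * 100.0 / rate
    return FrameSequence(frames, p, t)


class TestWindowFrames:
    def test_thirty_second_scan_partitions_into_six(self):
        wins = window_frames(_sequence(360), 5.0, 12.0)
        assert len(wins) == 6
        assert all(len(w) == 60 for w in wins)

    def test_exact_single_window(self):
        wins = window_frames(_sequence(60), 5.0, 12.0)
        assert len(wins) == 1 and len(wins[0]) == 60

    def test_trailing_partial_window_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            wins = window_frames(_sequence(70), 5.0, 12.0)
        assert len(wins) == 1 and len(wins[0]) == 60
        assert "10" in caplog.text

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="window"):
            window_frames(_sequence(30), 5.0, 12.0)

    def test_frame_rate_inferred_from_timestamps(self):
        wins = window_frames(_sequence(120), 5.0)
        assert len(wins) == 2


class TestPlaceFrame:
    def test_origin_column_lands_at_sheet_position(self, small_config):
        frame = np.ones((32, 32))
        x, y, z, vals = place_frame(frame, 130.0, small_config)
        assert x[0] == 0.0 and z[0] == 130.0
        assert vals is frame

    def test_shear_preserves_position_differences(self, small_config):
        frame = np.ones((32, 32))
        _, _, z1, _ = place_frame(frame, 100.0, small_config)
        _, _, z2, _ = place_frame(frame, 100.0 + 100.0 / 12.0, small_config)
        assert np.allclose(z2 - z1, 100.0 / 12.0)

    def test_far_column_projection(self):
        cfg = SystemConfig()
        frame = np.ones((512, 512))
        x, _, z, _ = place_frame(frame, 10.0, cfg)
        # last pixel center sits at 511*dy along the sheet
        m_last = 511 * 420.0 / 512
        assert x[-1] == pytest.approx(m_last / np.sqrt(2))
        assert z[-1] == pytest.approx(10.0 + m_last / np.sqrt(2))

    def test_out_of_chamber_position_rejected(self, small_config):
        with pytest.raises(ValueError, match="chamber"):
            place_frame(np.ones((32, 32)), 2000.0, small_config)


class TestReconstructVolume:
    def test_blob_centroid_recovered(self, small_config, full_track):
        scene = PlumeScene(chamber_dims_mm=small_config.chamber_dims_mm,
                           source_duration_s=40.0)
        seq, gts = simulate_scan(scene, full_track, 5.0, small_config,
                                 gain=1e8, freeze_time=True, t_start_s=25.0)
        bg = BackgroundModel.from_frames(
            [np.zeros((small_config.sensor_pixels,) * 2)])
        frames = [RawFrame(f, t, p) for f, t, p in
                  zip(seq.frames, seq.timestamps_s, seq.positions_mm)]
        proc = process_frames(frames, bg, small_config)
        vol = reconstruct_volume(window_frames(proc, 5.0, 12.0)[0], small_config)
        gt = gts[0]
        mask = vol.measured_mask
        gt_masked = VoxelVolume(np.where(mask, gt.values, np.nan),
                                gt.spacing_mm, gt.origin_mm, gt.window_s)
        diff = np.abs(vol.centroid_mm() - gt_masked.centroid_mm())
        assert np.all(diff <= np.asarray(vol.spacing_mm))

    def test_uniform_scene_round_trip(self, small_config, full_track):
        scene = PlumeScene(emission_rate=0.0, uniform_concentration=2.0,
                           chamber_dims_mm=small_config.chamber_dims_mm)
        seq, _ = simulate_scan(scene, full_track, 5.0, small_config,
                               gain=500.0, freeze_time=True)
        bg = BackgroundModel.from_frames(
            [np.zeros((small_config.sensor_pixels,) * 2)])
        frames = [RawFrame(f, t, p) for f, t, p in
                  zip(seq.frames, seq.timestamps_s, seq.positions_mm)]
        proc = process_frames(frames, bg, small_config)
        vol = reconstruct_volume(window_frames(proc, 5.0, 12.0)[0], small_config)
        meas = vol.values[vol.measured_mask]
        assert meas.std() / meas.mean() < 0.01
        # mean-intensity bookkeeping: hit-averaging preserves the mean level
        assert meas.mean() == pytest.approx(proc.frames.mean(), rel=0.01)

    def test_empty_chamber_all_zero(self, small_config):
        n = 60
        seq = FrameSequence(np.zeros((n, 32, 32)),
                            np.arange(n) * 100.0 / 12.0, np.arange(n) / 12.0)
        vol = reconstruct_volume(seq, small_config)
        assert np.all(vol.values[vol.measured_mask] == 0.0)
        assert np.any(~vol.measured_mask)  # sheared corners are marked missing

    def test_global_scale_equivariance(self, small_config, rng):
        n = 24
        frames = rng.uniform(0, 10, (n, 32, 32))
        seq = FrameSequence(frames, np.arange(n) * 100.0 / 12.0, np.arange(n) / 12.0)
        v1 = reconstruct_volume(seq, small_config)
        v2 = reconstruct_volume(FrameSequence(3.0 * frames, seq.positions_mm,
                                              seq.timestamps_s), small_config)
        m = v1.measured_mask
        assert np.array_equal(m, v2.measured_mask)
        assert np.allclose(v2.values[m], 3.0 * v1.values[m])

    def test_extents_within_measurement_volume(self, standard_config):
        n = 60
        seq = FrameSequence(np.zeros((n, 512, 512)),
                            np.arange(n) * 100.0 / 12.0, np.arange(n) / 12.0)
        vol = reconstruct_volume(seq, standard_config)
        nx, ny, _ = vol.values.shape
        assert (nx - 1) * vol.spacing_mm[0] <= 297.0
        assert (ny - 1) * vol.spacing_mm[1] <= 420.0
        assert seq.positions_mm.max() - seq.positions_mm.min() <= 500.0

    def test_stationary_platform_single_slice_with_warning(self, small_config):
        n = 5
        seq = FrameSequence(np.ones((n, 32, 32)), np.full(n, 100.0),
                            np.arange(n) / 12.0)
        with pytest.warns(UserWarning, match="single-slice"):
            vol = reconstruct_volume(seq, small_config)
        assert np.isfinite(vol.values).any()


class TestSweepDirectionMerge:
    def _static_sweeps(self, small_config, full_track):
        scene = PlumeScene(chamber_dims_mm=small_config.chamber_dims_mm,
                           source_duration_s=40.0)
        fwd, _ = simulate_scan(scene, full_track, 5.0, small_config,
                               gain=1e6, freeze_time=True, t_start_s=30.0)
        back_track = PlatformTrajectory(start_position_mm=fwd.positions_mm[-1],
                                        speed_mm_s=100.0, direction=-1,
                                        turnaround_high_mm=500.0)
        rev, _ = simulate_scan(scene, back_track, 5.0, small_config,
                               gain=1e6, freeze_time=True, t_start_s=30.0)
        rev = FrameSequence(rev.frames, rev.positions_mm, rev.timestamps_s + 5.0)
        return fwd, rev

    def test_direction_invariance_on_static_scene(self, small_config, full_track):
        fwd, rev = self._static_sweeps(small_config, full_track)
        merged = sweep_direction_merge([fwd, rev])
        wins = window_frames(merged, 5.0, 12.0)
        v1 = reconstruct_volume(wins[0], small_config)
        v2 = reconstruct_volume(wins[1], small_config)
        m = v1.measured_mask & v2.measured_mask
        a, b = v1.values[m], v2.values[m]
        scale = max(np.abs(a).max(), 1e-12)
        assert np.abs(a - b).max() / scale < 0.01

    def test_unordered_input_rejected(self, small_config, full_track):
        fwd, rev = self._static_sweeps(small_config, full_track)
        with pytest.raises(ValueError, match="chronological"):
            sweep_direction_merge([rev, fwd])

    def test_merge_preserves_counts(self, small_config, full_track):
        fwd, rev = self._static_sweeps(small_config, full_track)
        merged = sweep_direction_merge([fwd, rev])
        assert len(merged) == len(fwd) + len(rev)
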