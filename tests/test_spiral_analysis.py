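"""Spiral-wave analysis tests against synthetic ground truth: tip
detection, trajectory linking, signed spectra, phase-singularity counting
and APD/alternans mapping."""

import numpy as np
import pytest

from pigatria.spiral_analysis import (TipTrajectory, apd_map_and_alternans,
                                      count_phase_singularities, link_tips,
                                      track_tip, trajectory_spectrum)
from pigatria.synthetic import (ap_train_frames, hypocycloid_trajectory,
                                multi_singularity_frames, plane_wave_frames,
                                spiral_voltage_frames)

DX = 0.022


class TestTipTracking:
    def test_plane_wave_has_no_tip(self):
        _, frames = plane_wave_frames(n=64, dx=DX)
        assert track_tip(frames[2], frames[1], DX) == []

    def test_synthetic_spiral_tip_found_near_core(self):
        _, frames = spiral_voltage_frames(n=96, dx=DX, period_ms=180.0)
        core = (96 // 2 * DX, 96 // 2 * DX)
        tips = track_tip(frames[3], frames[2], DX)
        assert tips, "no tip detected on rotating spiral"
        d = min(np.hypot(x - core[0], y - core[1]) for x, y in tips)
        assert d < 2 * DX

    def test_tip_error_shrinks_with_grid_refinement(self):
        errs = {}
        for n, dx in ((64, 0.044), (128, 0.022)):
            _, frames = spiral_voltage_frames(
                n=n, dx=dx, period_ms=180.0, core=(1.4, 1.4),
                core_radius_cm=0.02)
            tips = track_tip(frames[4], frames[3], dx)
            errs[dx] = min(np.hypot(x - 1.4, y - 1.4) for x, y in tips)
        assert errs[0.022] < errs[0.044]

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            track_tip(np.zeros((4, 4)), np.zeros((5, 5)), DX)


class TestLinking:
    def test_continuous_tip_is_linked_into_one_track(self):
        times, frames = spiral_voltage_frames(
            n=96, dx=DX, period_ms=180.0,
            times_ms=np.arange(0.0, 200.0, 10.0))
        tip_lists = [track_tip(frames[k], frames[k - 1], DX)
                     for k in range(1, len(frames))]
        tracks = link_tips(times[1:], tip_lists)
        assert len(tracks[0]) >= 0.8 * (len(frames) - 1)
        steps = np.hypot(np.diff(tracks[0].x), np.diff(tracks[0].y))
        assert np.all(steps < 1.0)  # linking sanity gate

    def test_jump_beyond_gate_spawns_new_track(self):
        times = np.array([0.0, 10.0, 20.0, 30.0])
        tip_lists = [[(1.0, 1.0)], [(1.05, 1.0)],
                     [(5.0, 5.0)], [(5.05, 5.0)]]
        tracks = link_tips(times, tip_lists, gate_cm_per_frame=1.0)
        assert len(tracks) == 2
        assert all(len(tr) == 2 for tr in tracks)

    def test_trajectory_times_must_increase(self):
        with pytest.raises(ValueError):
            TipTrajectory(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2), 10.0)


class TestSpectrum:
    def test_counterclockwise_circle_gives_positive_frequency(self):
        traj = hypocycloid_trajectory(f0_hz=2.0, f1_hz=0.0, r0_cm=1.0,
                                      r1_cm=0.0, duration_ms=3000.0)
        m = trajectory_spectrum(traj, n_peaks=1)
        assert m.frequencies[0] == pytest.approx(2.0, abs=0.05)

    def test_clockwise_circle_gives_negative_frequency(self):
        traj = hypocycloid_trajectory(f0_hz=-2.0, f1_hz=0.0, r0_cm=1.0,
                                      r1_cm=0.0, duration_ms=3000.0)
        m = trajectory_spectrum(traj, n_peaks=1)
        assert m.frequencies[0] == pytest.approx(-2.0, abs=0.05)

    def test_two_counter_rotating_phasors_resolved_with_signed_peaks(self):
        """Superposed orbits at +f0 and -f1 with r0 > r1 give two spectral
        peaks whose signed positions and amplitude ordering match."""
        traj = hypocycloid_trajectory(f0_hz=4.0, f1_hz=-2.5, r0_cm=0.8,
                                      r1_cm=0.4, duration_ms=8000.0)
        m = trajectory_spectrum(traj, n_peaks=2)
        assert m.frequencies[0] == pytest.approx(4.0, abs=0.05)
        assert m.frequencies[1] == pytest.approx(-2.5, abs=0.05)
        assert m.amplitudes[0] > m.amplitudes[1]
        ratio = m.amplitudes[0] / m.amplitudes[1]
        assert ratio == pytest.approx(0.8 / 0.4, rel=0.1)

    def test_published_meander_frequencies_recovered(self):
        """The meander pattern built from the reported signed frequencies
        (+5.426 / -3.548 Hz) is recovered by the spectrum, with rotation
        period ~184 ms from the dominant peak."""
        traj = hypocycloid_trajectory()  # defaults: 5.426 / -3.548 Hz
        m = trajectory_spectrum(traj)
        assert m.frequencies[0] == pytest.approx(5.426, abs=0.15)
        assert m.frequencies[1] == pytest.approx(-3.548, abs=0.15)
        assert m.rotation_period == pytest.approx(1000.0 / 5.426, rel=0.03)

    def test_short_trajectory_rejected(self):
        traj = hypocycloid_trajectory(duration_ms=60.0)
        with pytest.raises(ValueError):
            trajectory_spectrum(traj)


class TestPhaseSingularities:
    def test_plane_wave_has_zero_singularities(self):
        _, frames = plane_wave_frames(n=64, dx=DX)
        assert np.all(count_phase_singularities(frames)[1:] == 0)

    def test_single_spiral_has_one_singularity(self):
        _, frames = spiral_voltage_frames(n=96, dx=DX, period_ms=180.0)
        counts = count_phase_singularities(frames)
        assert np.all(counts[1:] == 1)

    def test_opposite_pair_counts_two_with_zero_net_winding(self):
        _, frames = multi_singularity_frames([(1.0, 1.0), (2.0, 2.0)],
                                             [1, -1])
        counts = count_phase_singularities(frames)
        assert np.all(counts[1:] == 2)

    def test_eight_singularities_counted(self):
        cores = [(0.35 + 0.7 * i, 0.35 + 0.7 * j)
                 for i in range(3) for j in range(3)][:8]
        _, frames = multi_singularity_frames(cores, [1] * 8, n=128)
        counts = count_phase_singularities(frames)
        assert np.all(counts[1:] == 8)

    def test_needs_at_least_two_frames(self):
        with pytest.raises(ValueError):
            count_phase_singularities(np.zeros((1, 8, 8)))


class TestAPDMapAndAlternans:
    def test_strictly_periodic_train_has_no_alternans(self):
        t, frames = ap_train_frames([120.0] * 8, cl_ms=250.0)
        res = apd_map_and_alternans(t, frames, DX, sample_stride=8)
        assert res["sites"]
        assert res["alternans_fraction"] == 0.0
        apd = res["sites"][0]["apd90"]
        assert np.nanmax(np.abs(apd - 120.0)) < 5.0

    def test_long_short_alternation_is_flagged(self):
        seq = [130.0 if k % 2 == 0 else 110.0 for k in range(8)]
        t, frames = ap_train_frames(seq, cl_ms=250.0)
        res = apd_map_and_alternans(t, frames, DX, sample_stride=8)
        assert res["alternans_fraction"] == 1.0

    def test_restitution_pairs_report_cycle_length(self):
        t, frames = ap_train_frames([120.0] * 8, cl_ms=250.0)
        res = apd_map_and_alternans(t, frames, DX, sample_stride=8)
        cl = res["cl_apd90"][:, 0]
        assert np.allclose(cl, 250.0, atol=5.0)

    def test_silent_sites_are_excluded(self):
        t = np.arange(0.0, 500.0, 2.0)
        frames = np.full((len(t), 8, 8), -80.0)
        res = apd_map_and_alternans(t, frames, DX, sample_stride=8)
        assert res["sites"] == []

    def test_sites_near_excluded_points_are_dropped(self):
        t, frames = ap_train_frames([120.0] * 8, cl_ms=250.0, n=8)
        res = apd_map_and_alternans(t, frames, DX, sample_stride=8,
                                    exclude_points=[(0.0, 0.0)],
                                    exclude_center_cm=1.0)
        assert res["sites"] == []  # the only sampled site sits at the origin


class TestPetalCount:
    def test_published_meander_pattern_has_five_petals(self):
        """The counter-rotating meander components at +5.426 / -3.548 Hz
        close a five-petaled flower."""
        traj = hypocycloid_trajectory(duration_ms=10_000.0)
        m = trajectory_spectrum(traj)
        assert m.petal_count == 5

    def test_single_rotation_direction_has_no_petal_count(self):
        from pigatria.spiral_analysis import estimate_petal_count
        assert estimate_petal_count([3.0, 1.5]) is None
        assert estimate_petal_count([3.0]) is None
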