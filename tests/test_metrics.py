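"""Derived statistics: distances, events, speeds, MSD, geometry, phases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centrodyn import metrics as M
from centrodyn.synth import TrajectoryProgram, ellipse_boundary, simulate_pair


def track_from(xy, frames=None):
    xy = np.asarray(xy, float)
    frames = np.arange(len(xy)) if frames is None else np.asarray(frames)
    return pd.DataFrame({"frame": frames, "x": xy[:, 0], "y": xy[:, 1]})


def truth_tracks(truth):
    out = []
    for cid in (0, 1):
        sub = truth.table[truth.table.centrosome_id == cid]
        out.append(track_from(sub[["x_um", "y_um"]].to_numpy(),
                              sub.frame.to_numpy()))
    return out


class TestDistanceSeries:
    def test_identical_tracks_zero(self):
        t = track_from([(1, 2), (3, 4), (5, 6)])
        assert np.allclose(M.distance_series(t, t), 0.0)

    def test_pythagorean_offset(self):
        a = track_from([(0, 0), (1, 1), (2, 2)])
        b = track_from([(3, 4), (4, 5), (5, 6)])
        assert np.allclose(M.distance_series(a, b), 5.0)

    def test_programmed_relative_speed_increments(self, scene):
        # relative speed 0.2 μm/min at 5-min frames → +1 μm per frame
        truth = simulate_pair(
            TrajectoryProgram(mode="separation", speeds_um_min=(0.1, 0.1),
                              onset_frame=0),
            scene, seed=1, n_frames=8,
        )
        a, b = truth_tracks(truth)
        d = M.distance_series(a, b)
        inc = np.diff(d.to_numpy())
        growing = inc[inc > 1e-9]
        assert np.allclose(growing[:-1], 1.0, atol=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = track_from(rng.uniform(0, 10, (6, 2)))
        b = track_from(rng.uniform(0, 10, (6, 2)))
        pd.testing.assert_series_equal(M.distance_series(a, b),
                                       M.distance_series(b, a))


class TestEvents:
    def test_onset_at_sustained_jump(self):
        d = pd.Series([0.5] * 6 + [3.0] * 6, index=range(12))
        assert M.detect_separation_onset(d, 2.5, 2) == 6

    def test_no_onset_below_threshold(self):
        d = pd.Series([0.5, 1.0, 2.0, 2.4], index=range(4))
        assert M.detect_separation_onset(d, 2.5, 2) is None

    def test_single_frame_spike_not_onset(self):
        d = pd.Series([0.5, 3.0, 0.5, 0.5, 0.5], index=range(5))
        assert M.detect_separation_onset(d, 2.5, 2) is None

    def test_contact_with_dwell(self):
        d = pd.Series([5, 4, 3, 2, 1.0, 1.0, 1.0], index=range(7))
        frame, congressed = M.time_of_first_contact(d, 1.5, 2)
        assert frame == 4 and congressed

    def test_one_frame_dip_not_contact(self):
        d = pd.Series([5, 4, 1.0, 4, 5], index=range(5))
        frame, congressed = M.time_of_first_contact(d, 1.5, 2)
        assert frame is None and not congressed

    def test_phase_labels_pre_active_post(self):
        d = pd.Series([1, 1, 4, 7, 10, 10, 10], index=range(7), dtype=float)
        onset = M.detect_separation_onset(d, 2.5, 2)
        labels = M.label_phases(d, onset)
        assert list(labels) == ["pre", "pre", "active", "active", "active",
                                "post", "post"]


class TestPercentCongression:
    def test_fourteen_of_twenty_plateau(self):
        times = np.arange(0, 100, 5)
        contacts = [10.0] * 14 + [None] * 6
        pc = M.percent_congression(contacts, times)
        assert pc[-1] == pytest.approx(70.0)
        assert pc[0] == 0.0

    def test_none_congress(self):
        pc = M.percent_congression([None] * 5, np.arange(10))
        assert np.all(pc == 0.0)

    def test_all_congress_by_frame_three(self):
        pc = M.percent_congression([3.0, 2.0, 3.0], np.arange(6))
        assert np.all(pc[3:] == 100.0)

    def test_monotone_in_time_and_threshold(self):
        rng = np.random.default_rng(2)
        times = np.arange(0, 200, 5.0)
        d_series = []
        for _ in range(10):
            d = 10 - 0.08 * times + rng.normal(0, 0.3, len(times))
            d_series.append(pd.Series(np.clip(d, 0, None), index=range(len(times))))
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.0, 3.0):
            contacts = [
                (t * 5.0 if t is not None else None)
                for t, _c in (M.time_of_first_contact(d, thr, 2) for d in d_series)
            ]
            pc = M.percent_congression(contacts, times)
            assert np.all(np.diff(pc) >= 0)  # monotone in time
            if prev is not None:
                assert np.all(pc >= prev)    # monotone in threshold
            prev = pc


class TestSpeeds:
    def test_constant_speed_track(self):
        xy = [(0.5 * f, 0.0) for f in range(10)]  # 0.5 μm/frame at 5 min
        assert M.path_speed(track_from(xy), 5.0) == pytest.approx(0.1)

    def test_stationary_zero(self):
        assert M.path_speed(track_from([(1, 1)] * 8), 5.0) == 0.0

    def test_windowed_piecewise_speed(self):
        # 0.4 μm/min for 5 frames then stopped; restricting to the active
        # window recovers 0.4
        xy = [(2.0 * f, 0.0) for f in range(6)] + [(10.0, 0.0)] * 5
        t = track_from(xy)
        assert M.path_speed(t, 5.0, frames=(0, 5)) == pytest.approx(0.4)
        assert M.path_speed(t, 5.0) < 0.4

    def test_approach_speed_from_distance(self):
        d = pd.Series([10, 8, 6, 4], index=range(4), dtype=float)
        assert M.approach_speed(d, 5.0) == pytest.approx(0.4)


class TestMSD:
    def test_stationary_zero(self):
        m = M.msd(track_from([(2, 3)] * 12), 5.0)
        assert np.allclose(m.dropna(), 0.0)

    def test_constant_velocity_quadratic(self):
        v = 0.2  # μm/min; 5-min frames
        xy = [(v * 5.0 * f, 0.0) for f in range(15)]
        m = M.msd(track_from(xy), 5.0)
        for tau, val in m.items():
            assert val == pytest.approx((v * tau) ** 2, abs=1e-12)

    def test_random_walk_linear_slope(self):
        """Time-averaged MSD of a 2D random walk ≈ 2σ²·(τ/Δt) over 100
        seeded walks (Monte-Carlo oracle)."""
        sigma = 0.3
        dt = 5.0
        curves = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            steps = rng.normal(0, sigma, (60, 2))
            xy = np.cumsum(steps, axis=0)
            curves.append(M.msd(track_from(xy), dt))
        mean = pd.concat(curves, axis=1).mean(axis=1)
        for tau in mean.index[1:]:
            expected = 2 * sigma**2 * (tau / dt)
            assert mean[tau] == pytest.approx(expected, rel=0.15)

    def test_gapped_track_uses_actual_lags(self):
        xy = [(1.0 * f, 0.0) for f in range(10)]
        t = track_from(xy).drop(index=4)  # missing frame 4
        m = M.msd(t, 1.0, max_lag=3)
        assert m[1.0] == pytest.approx(1.0)
        assert m[2.0] == pytest.approx(4.0)


class TestDisplacementGrouping:
    def test_moving_centrosome_is_high(self):
        still = M.msd(track_from([(0, 0)] * 12), 5.0)
        moving = M.msd(track_from([(0.5 * f, 0) for f in range(12)]), 5.0)
        assignment, cohort = M.displacement_grouping([(still, moving)])
        assert assignment == [("low", "high")]
        assert (cohort["high_mean"].dropna() >= cohort["low_mean"].dropna()).all()

    def test_tie_breaks_to_first(self):
        m = M.msd(track_from([(0.1 * f, 0) for f in range(10)]), 5.0)
        assignment, _ = M.displacement_grouping([(m, m.copy())])
        assert assignment == [("high", "low")]

    def test_cohort_three_to_one_ratio(self):
        curves = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            fast = np.cumsum(rng.normal(0, 0.6, (30, 2)), axis=0)
            slow = np.cumsum(rng.normal(0, 0.2, (30, 2)), axis=0)
            curves.append((M.msd(track_from(fast), 5.0),
                           M.msd(track_from(slow), 5.0)))
        _, cohort = M.displacement_grouping(curves)
        valid = cohort.dropna()
        assert (valid["high_mean"].iloc[1:] > valid["low_mean"].iloc[1:]).all()


class TestGeometry:
    def test_diametric_angle_180(self):
        assert M.centroid_angle((0, 5), (0, -5), (0, 0)) == pytest.approx(180.0)

    def test_perpendicular_angle_90(self):
        assert M.centroid_angle((1, 0), (0, 1), (0, 0)) == pytest.approx(90.0)

    def test_coincident_with_centroid_raises(self):
        with pytest.raises(ValueError):
            M.centroid_angle((0, 0), (1, 1), (0, 0))

    @settings(max_examples=25, deadline=None)
    @given(theta=st.floats(0.1, 179.9), rot=st.floats(0, 360),
           tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_angle_invariant_under_rigid_motion(self, theta, rot, tx, ty):
        c = np.array([0.0, 0.0])
        p1 = np.array([4.0, 0.0])
        a = np.radians(theta)
        p2 = 6.0 * np.array([np.cos(a), np.sin(a)])
        r = np.radians(rot)
        R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t = np.array([tx, ty])
        before = M.centroid_angle(p1, p2, c)
        after = M.centroid_angle(R @ p1 + t, R @ p2 + t, R @ c + t)
        assert after == pytest.approx(before, abs=1e-6)

    def test_midpoint_distance_examples(self):
        assert M.alignment_midpoint_distance((0, 5), (0, -5), (0, 0)) == 0.0
        assert M.alignment_midpoint_distance((2, 3), (2, 3), (0, 0)) == \
            pytest.approx(np.hypot(2, 3))
        assert M.alignment_midpoint_distance((8, 0), (0, 0), (0, 0)) == 4.0

    def test_axis_rotation_examples(self):
        pair = ((0, 0), (5, 0))
        assert M.axis_rotation(pair, pair) == pytest.approx(0.0)
        assert M.axis_rotation(pair, ((0, 0), (0, 3))) == pytest.approx(90.0)
        a = np.radians(30)
        rotated = ((0, 0), (5 * np.cos(a), 5 * np.sin(a)))
        assert M.axis_rotation(pair, rotated) == pytest.approx(30.0)
        # undirected: flipping one axis changes nothing
        assert M.axis_rotation(pair, ((5, 0), (0, 0))) == pytest.approx(0.0)

    def test_centroid_distance_series_hand_computed(self):
        t = track_from([(3, 4), (6, 8)])
        out = M.centroid_distance_series(t, (0, 0), (3, 0))
        assert np.allclose(out["dist_nuclear_um"], [5.0, 10.0])
        assert np.allclose(out["dist_cellular_um"], [4.0, np.hypot(3, 8)])


class TestNEPhases:
    def test_stalled_track_phase_speeds(self, scene):
        truth = simulate_pair(
            TrajectoryProgram(mode="stall_at_NE", speeds_um_min=(0.3, 0.3),
                              dwell_min=20.0),
            scene, seed=4, n_frames=30,
        )
        a, _ = truth_tracks(truth)
        phases = M.ne_contact_phases(a, scene.nucleus_boundary_um, 5.0,
                                     pause_window_min=20.0)
        assert phases.contact_frame is not None
        assert phases.outside_speed == pytest.approx(0.3, rel=0.05)
        assert phases.pause_speed < 0.1 * phases.outside_speed

    def test_track_never_reaching_nucleus(self):
        boundary = ellipse_boundary((0, 0), (5, 5))
        t = track_from([(20, 20), (21, 20), (22, 20)])
        phases = M.ne_contact_phases(t, boundary, 5.0)
        assert phases.contact_frame is None
        assert phases.pause_speed is None and phases.after_speed is None

    def test_contact_at_time_zero_no_outside_phase(self):
        boundary = ellipse_boundary((0, 0), (5, 5))
        t = track_from([(5.0, 0), (4.5, 0), (4.0, 0), (3.5, 0), (3.0, 0)])
        phases = M.ne_contact_phases(t, boundary, 5.0)
        assert phases.contact_frame == 0
        assert phases.outside_speed is None


class TestClassifyPosition:
    boundary = ellipse_boundary((0, 0), (9, 6))

    def test_diametric_under_nucleus(self):
        got = M.classify_position((7, 0), (-7, 0), (0, 0), self.boundary)
        assert got == "diametric-under-nucleus"

    def test_detached_far_outside(self):
        got = M.classify_position((19, 0), (0, 16), (0, 0), self.boundary)
        assert got == "detached"

    def test_ne_border_within_tolerance(self):
        got = M.classify_position((9.5, 0), (0, 6.5), (0, 0), self.boundary)
        assert got == "NE-border"

    def test_side_of_nucleus(self):
        got = M.classify_position((11.5, 0), (11.5, 2.0), (0, 0), self.boundary)
        assert got == "side-of-nucleus"


class TestComets:
    def test_stationary_blob_speed_near_zero(self):
        tracks = track_from([(5, 5)] * 8)
        tracks["track_id"] = 0
        stats = M.comet_stats(tracks, 1.0)
        assert stats["mean_speed_um_min"] == pytest.approx(0.0, abs=1e-9)

    def test_programmed_radial_speed_recovered(self, small_scene):
        from centrodyn.synth import simulate_comets

        truth = simulate_pair(TrajectoryProgram(mode="stationary"),
                              small_scene, seed=5)
        comets = simulate_comets(small_scene, truth, seed=5)
        comets = comets.rename(columns={"comet_id": "track_id",
                                        "x_um": "x", "y_um": "y"})
        stats = M.comet_stats(comets, small_scene.config.frame_interval_min)
        assert stats["mean_speed_um_min"] == pytest.approx(
            small_scene.config.comet_speed_um_min, rel=0.10)
        assert stats["n_tracks"] > 0
        assert stats["pooled_msd"] is not None
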