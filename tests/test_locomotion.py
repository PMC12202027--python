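"""Reference-point speed, episode segmentation, substrate correction, head pose."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import episodes_bruteforce, windowed_speed_bruteforce
from mocapkit.io import MarkerPairSpec, Task, Trajectory, TrialRecording
from mocapkit.locomotion import (
    SpeedSeries,
    detect_locomotion_episodes,
    head_orientation,
    hip_midpoint,
    surface_relative,
    trial_locomotion_summary,
    windowed_speed,
)

FS = 300.0


def _speed(values):
    return SpeedSeries(np.asarray(values, float), 100, FS)


class TestHipMidpoint:
    def test_arithmetic_midpoint(self):
        a = Trajectory(np.tile([0.0, 0, 0], (5, 1)), np.zeros(5, bool))
        b = Trajectory(np.tile([2.0, 0, 0], (5, 1)), np.zeros(5, bool))
        trial = TrialRecording(trial_id="t", task=Task.OF, markers={"hip_l": a, "hip_r": b})
        mid = hip_midpoint(trial)
        np.testing.assert_allclose(mid.positions, np.tile([1.0, 0, 0], (5, 1)))

    def test_missing_propagates(self):
        a = Trajectory(np.zeros((5, 3)), np.array([0, 0, 1, 0, 0], bool))
        b = Trajectory(np.ones((5, 3)), np.zeros(5, bool))
        trial = TrialRecording(trial_id="t", task=Task.OF, markers={"hip_l": a, "hip_r": b})
        assert hip_midpoint(trial).missing[2]

    def test_equidistant_from_random_rigid_pair(self, rng):
        d = 14.0
        offs = rng.normal(0, 40, size=(50, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        a = Trajectory.from_positions(offs - axis * d / 2)
        b = Trajectory.from_positions(offs + axis * d / 2)
        trial = TrialRecording(trial_id="t", task=Task.OF, markers={"hip_l": a, "hip_r": b})
        mid = hip_midpoint(trial)
        da = np.linalg.norm(mid.positions - a.positions, axis=1)
        db = np.linalg.norm(mid.positions - b.positions, axis=1)
        np.testing.assert_allclose(da, db)
        np.testing.assert_allclose(da, d / 2)

    def test_absent_labels_raise(self):
        trial = TrialRecording(trial_id="t", task=Task.OF, markers={})
        with pytest.raises(KeyError):
            hip_midpoint(trial)


class TestWindowedSpeed:
    def test_static_point_zero(self):
        traj = Trajectory.from_positions(np.tile([1.0, 2, 3], (400, 1)))
        v = windowed_speed(traj, 100, FS).values
        assert np.nanmax(v) == 0.0
        assert np.isnan(v[:50]).all() and np.isnan(v[-50:]).all()

    @pytest.mark.parametrize("window", [10, 30, 100, 301])
    def test_uniform_motion_exact(self, window):
        t = np.arange(900) / FS
        traj = Trajectory.from_positions(np.column_stack([60 * t, 0 * t, 0 * t]))
        v = windowed_speed(traj, window, FS).values
        np.testing.assert_allclose(v[np.isfinite(v)], 60.0)

    def test_sinusoid_matches_bruteforce(self):
        t = np.arange(700) / FS
        pos = np.column_stack(
            [30 * np.sin(2 * np.pi * 1.3 * t), 10 * np.cos(2 * np.pi * 0.7 * t), 5 * t]
        )
        pos[100:130] = np.nan
        traj = Trajectory.from_positions(pos)
        for w in (10, 30, 100):
            got = windowed_speed(traj, w, FS).values
            want = windowed_speed_bruteforce(pos, w, FS)
            np.testing.assert_allclose(got, want, equal_nan=True, atol=1e-9)


class TestEpisodeDetection:
    def test_flat_zero_speed(self):
        assert detect_locomotion_episodes(_speed(np.zeros(1000))) == []

    def test_minimal_episode(self):
        v = np.zeros(500)
        v[100:250] = 50.0
        eps = detect_locomotion_episodes(_speed(v))
        assert [(e.interval.start, e.interval.end) for e in eps] == [(100, 250)]
        assert eps[0].mean_speed == pytest.approx(50.0)

    def test_brief_dip_merged(self):
        v = np.concatenate([np.zeros(50), 50 * np.ones(80), 30 * np.ones(40),
                            50 * np.ones(80), np.zeros(50)])
        eps = detect_locomotion_episodes(_speed(v))
        assert [(e.interval.start, e.interval.end) for e in eps] == [(50, 250)]

    def test_long_dip_splits_and_short_segments_dropped(self):
        v = np.concatenate([50 * np.ones(120), np.zeros(51), 50 * np.ones(80)])
        eps = detect_locomotion_episodes(_speed(v))
        assert [(e.interval.start, e.interval.end) for e in eps] == [(0, 120)]

    def test_randomized_traces_match_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(50, 2000))
            v = rng.choice([0.0, 30.0, 50.0, 80.0], size=n,
                           p=[0.35, 0.15, 0.3, 0.2])
            v[rng.random(n) < 0.02] = np.nan
            thr, mn, dip = 40.0, int(rng.integers(20, 150)), int(rng.integers(0, 80))
            got = [
                (e.interval.start, e.interval.end)
                for e in detect_locomotion_episodes(_speed(v), thr, mn, dip)
            ]
            assert got == episodes_bruteforce(v, thr, mn, dip)

    def test_edge_padding_invariance(self):
        v = np.zeros(600)
        v[200:400] = 55.0
        base = detect_locomotion_episodes(_speed(v))
        padded = detect_locomotion_episodes(
            _speed(np.concatenate([np.full(100, 10.0), v]))
        )
        assert [(e.interval.start - 100, e.interval.end - 100) for e in padded] == [
            (e.interval.start, e.interval.end) for e in base
        ]

    def test_episodes_disjoint_and_sorted(self, rng):
        v = rng.choice([0.0, 60.0], size=3000)
        eps = detect_locomotion_episodes(_speed(v), 40, 50, 20)
        bounds = [(e.interval.start, e.interval.end) for e in eps]
        assert bounds == sorted(bounds)
        assert all(b1[1] < b2[0] for b1, b2 in zip(bounds, bounds[1:]))


class TestTrialSummary:
    def test_static_trial(self):
        traj = Trajectory.from_positions(np.tile([0.0, 0, 0], (3000, 1)))
        s = trial_locomotion_summary(traj, [], windowed_speed(traj, 300, FS))
        assert s["distance_traveled_mm"] == 0.0
        assert s["time_locomoting_s"] == 0.0
        assert s["mean_locomotory_speed_mm_s"] is None

    def test_uniform_motion_totals(self):
        n = int(60 * FS)
        t = np.arange(n) / FS
        traj = Trajectory.from_positions(np.column_stack([50 * t, 0 * t, 0 * t]))
        speed = windowed_speed(traj, 100, FS)
        eps = detect_locomotion_episodes(speed, reference=traj)
        s = trial_locomotion_summary(traj, eps, speed)
        # n frames span (n-1) displacement steps, one frame short of 60 s
        assert s["distance_traveled_mm"] == pytest.approx(50 * 60, abs=0.2)
        # the centered window is undefined in the first/last half window
        assert s["time_locomoting_s"] == pytest.approx(60.0, abs=0.35)
        assert s["mean_locomotory_speed_mm_s"] == pytest.approx(50.0)


class TestSurfaceRelative:
    def _belt_trial(self, mouse_matches_belt):
        n = 900
        t = np.arange(n) / FS
        belt_v = 120.0
        belt_disp = belt_v * t  # belt surface moves along -x at belt_v
        mouse_x = -belt_disp if not mouse_matches_belt else np.zeros(n)
        # a stationary-in-lab mouse is carried backward relative to the belt
        markers = {}
        for lab, off in (("hip_l", [0, -7, 30]), ("hip_r", [0, 7, 30])):
            pos = np.column_stack(
                [np.zeros(n) + off[0], np.full(n, off[1]), np.full(n, off[2])]
            )
            if mouse_matches_belt:
                pos[:, 0] -= belt_disp  # rides the belt backwards
            markers[lab] = Trajectory.from_positions(pos)
        surface = {}
        loop = 600.0
        for j in range(3):
            x = np.mod(j * 200.0 - belt_disp + 150.0, loop) - 150.0
            pos = np.column_stack([x, np.full(n, 30.0), np.zeros(n)])
            missing = np.abs(x) > 150.0
            pos[missing] = np.nan
            surface[f"belt_{j}"] = Trajectory(pos, missing)
        return TrialRecording(
            trial_id="belt", task=Task.TRM, markers=markers, surface_markers=surface
        )

    def test_stationary_mouse_on_moving_belt(self):
        rel = surface_relative(self._belt_trial(mouse_matches_belt=False))
        v = windowed_speed(hip_midpoint(rel), 100, FS).values
        assert np.nanmedian(v) == pytest.approx(120.0, rel=0.02)

    def test_mouse_riding_belt_has_zero_relative_speed(self):
        rel = surface_relative(self._belt_trial(mouse_matches_belt=True))
        v = windowed_speed(hip_midpoint(rel), 100, FS).values
        assert np.nanmedian(v) == pytest.approx(0.0, abs=1.0)

    def test_wheel_rotation_gives_tangential_speed(self):
        n = 900
        t = np.arange(n) / FS
        omega = 1.2  # rad/s
        center = np.array([0.0, 0.0, 250.0])
        r = 125.0
        surface = {}
        for j in range(8):
            psi = j * np.pi / 4 + omega * t
            pos = np.column_stack(
                [r * np.sin(psi), np.full(n, -25.0), 250.0 - r * np.cos(psi)]
            )
            surface[f"rim_{j}"] = Trajectory.from_positions(pos)
        radius_m = 140.0
        fixed = np.tile(center + [radius_m, 0.0, 0.0], (n, 1))
        markers = {
            "hip_l": Trajectory.from_positions(fixed + [0, -7, 0]),
            "hip_r": Trajectory.from_positions(fixed + [0, 7, 0]),
        }
        trial = TrialRecording(
            trial_id="wheel", task=Task.CLB, markers=markers, surface_markers=surface
        )
        rel = surface_relative(trial)
        v = windowed_speed(hip_midpoint(rel), 30, FS).values
        assert np.nanmedian(v) == pytest.approx(omega * radius_m, rel=0.02)

    def test_zero_surface_motion_is_identity(self):
        trial = self._belt_trial(mouse_matches_belt=False)
        for tr in trial.surface_markers.values():
            tr.positions[:, 0] = np.linspace(-100, -100, len(tr))
            tr.missing[:] = False
        rel = surface_relative(trial)
        for lab in trial.markers:
            np.testing.assert_allclose(
                rel.markers[lab].positions, trial.markers[lab].positions, atol=1e-9
            )

    def test_requires_surface_markers(self):
        trial = TrialRecording(
            trial_id="t", task=Task.TRM,
            markers={"hip_l": Trajectory.from_positions(np.zeros((10, 3)))},
        )
        with pytest.raises(ValueError, match="surface"):
            surface_relative(trial)


class TestHeadOrientation:
    TEMPLATE = {
        "front_l": np.array([5.0, 4.0, 0.0]),
        "front_r": np.array([5.0, -4.0, 0.0]),
        "back_l": np.array([-5.0, 4.0, 0.0]),
        "back_r": np.array([-5.0, -4.0, 0.0]),
    }

    def _posed(self, rot: Rotation, n=5):
        return {
            lab: Trajectory.from_positions(np.tile(rot.apply(p), (n, 1)))
            for lab, p in self.TEMPLATE.items()
        }

    def test_identity_pose(self):
        pose = head_orientation(self._posed(Rotation.identity()))
        np.testing.assert_allclose(pose.yaw, 0.0, atol=1e-9)
        np.testing.assert_allclose(pose.pitch, 0.0, atol=1e-9)
        np.testing.assert_allclose(pose.roll, 0.0, atol=1e-9)

    def test_pure_yaw(self):
        pose = head_orientation(self._posed(Rotation.from_euler("z", 90, degrees=True)))
        np.testing.assert_allclose(pose.yaw, 90.0, atol=1e-9)
        np.testing.assert_allclose(pose.pitch, 0.0, atol=1e-9)

    def test_random_rotation_round_trip(self, rng):
        for _ in range(20):
            ypr = [rng.uniform(-170, 170), rng.uniform(-80, 80), rng.uniform(-80, 80)]
            rot = Rotation.from_euler("ZYX", ypr, degrees=True)
            pose = head_orientation(self._posed(rot))
            np.testing.assert_allclose(
                [pose.yaw[0], pose.pitch[0], pose.roll[0]], ypr, atol=1e-6
            )

    def test_collinear_markers_undefined(self):
        markers = {
            lab: Trajectory.from_positions(np.tile([i * 1.0, 0, 0], (3, 1)))
            for i, lab in enumerate(["front_l", "front_r", "back_l"])
        }
        pose = head_orientation(markers)
        assert np.isnan(pose.yaw).all()
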