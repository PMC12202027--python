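"""Reference-point speed, locomotory episodes, substrate correction, head pose.

General locomotion is tracked through the midpoint of the two hip markers.
Its speed is the 3D displacement over a centered window divided by the window
duration; the standard scales are a 1 s window for reported speeds and a
100-frame (~300 ms) window for locomotion-onset detection.  A locomotory
episode is a maximal period with speed above 40 mm/s lasting at least 100
frames, tolerating interior dips below threshold of up to 50 frames; episodes
begin and end on supra-threshold frames.

On the treadmill and climbing wheel, displacement is re-expressed relative to
the moving substrate, tracked by belt or rim markers.  Head orientation is
derived from >=3 headplate corner markers by per-frame plane fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

from .io import FrameInterval, Task, Trajectory, TrialRecording

__all__ = [
    "SpeedSeries",
    "LocomotionEpisode",
    "HeadPose",
    "hip_midpoint",
    "windowed_speed",
    "detect_locomotion_episodes",
    "trial_locomotion_summary",
    "surface_relative",
    "head_orientation",
    "episode_mask",
    "DEFAULT_SPEED_THRESHOLD_MM_S",
    "DEFAULT_MIN_EPISODE_FRAMES",
    "DEFAULT_MAX_DIP_FRAMES",
    "DEFAULT_ONSET_WINDOW_FRAMES",
    "HIP_LABELS",
]

DEFAULT_SPEED_THRESHOLD_MM_S = 40.0
DEFAULT_MIN_EPISODE_FRAMES = 100
DEFAULT_MAX_DIP_FRAMES = 50
DEFAULT_ONSET_WINDOW_FRAMES = 100  # ~300 ms at 300 fps
HIP_LABELS = ("hip_l", "hip_r")


class Alignment(str, Enum):
    CENTERED = "centered"
    TRAILING = "trailing"


@dataclass
class SpeedSeries:
    """Per-frame speed (mm/s); NaN where the window is not fully observed."""

    values: np.ndarray
    window_frames: int
    frame_rate: float
    alignment: Alignment = Alignment.CENTERED

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class LocomotionEpisode:
    interval: FrameInterval
    mean_speed: float  # mm/s over the episode's frames
    distance: float  # mm travelled by the reference point within the episode

    @property
    def duration_frames(self) -> int:
        return self.interval.duration


@dataclass
class HeadPose:
    """Per-frame yaw/pitch/roll (degrees, z-y'-x'' convention) of the head plane."""

    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    plane_center: np.ndarray  # (n, 3) mm


def hip_midpoint(trial: TrialRecording, labels: tuple[str, str] = HIP_LABELS) -> Trajectory:
    """Arithmetic midpoint of the two hip markers; missing if either hip is."""
    for lab in labels:
        if lab not in trial.markers:
            raise KeyError(f"hip marker {lab!r} absent from trial")
    a, b = (trial.markers[lab] for lab in labels)
    mid = 0.5 * (a.positions + b.positions)
    missing = a.missing | b.missing
    mid = mid.copy()
    mid[missing] = np.nan
    return Trajectory(
        positions=mid, missing=missing, filled=(a.filled | b.filled) & ~missing
    )


def windowed_speed(
    traj: Trajectory,
    window_frames: int,
    frame_rate: float,
    alignment: Alignment | str = Alignment.CENTERED,
    dims: int = 3,
) -> SpeedSeries:
    """Speed from the displacement across a window of ``window_frames`` frames.

    Centered alignment measures ``||p(t + w/2) - p(t - w/2)|| / (w / fps)``
    using integer half-windows (so the effective span is ``2 * (w // 2)``
    frames); trailing uses ``p(t) - p(t - w)``.  Frames whose window endpoints
    are missing or out of range are NaN.  ``dims=2`` restricts the
    displacement to the horizontal (x, y) plane.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    alignment = Alignment(alignment)
    n = len(traj)
    pos = traj.positions[:, :dims]
    out = np.full(n, np.nan)
    if alignment is Alignment.CENTERED:
        h = max(window_frames // 2, 1)
        span = 2 * h
        if n > span:
            disp = np.linalg.norm(pos[span:] - pos[:-span], axis=1)
            out[h:n - h] = disp / (span / frame_rate)
    else:
        w = window_frames
        if n > w:
            disp = np.linalg.norm(pos[w:] - pos[:-w], axis=1)
            out[w:] = disp / (w / frame_rate)
    return SpeedSeries(out, window_frames, frame_rate, alignment)


def detect_locomotion_episodes(
    speed: SpeedSeries,
    threshold_mm_s: float = DEFAULT_SPEED_THRESHOLD_MM_S,
    min_frames: int = DEFAULT_MIN_EPISODE_FRAMES,
    max_dip_frames: int = DEFAULT_MAX_DIP_FRAMES,
    reference: Trajectory | None = None,
) -> list[LocomotionEpisode]:
    """Segment maximal supra-threshold intervals with bounded interior dips.

    Sub-threshold (or undefined) runs of up to ``max_dip_frames`` frames are
    tolerated inside an episode but cannot begin or end one; the minimum
    length applies to the merged interval including dips.  If ``reference``
    is given, per-episode distance is the summed frame-to-frame displacement
    of that trajectory.
    """
    if threshold_mm_s <= 0 or min_frames <= 0 or max_dip_frames < 0:
        raise ValueError("thresholds must be positive")
    v = speed.values
    above = np.zeros(len(v), dtype=bool)
    defined = np.isfinite(v)
    above[defined] = v[defined] > threshold_mm_s
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    # merge supra-threshold runs separated by dips <= max_dip_frames
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= max_dip_frames:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    episodes = []
    for s, e in merged:
        if e - s < min_frames:
            continue
        seg = v[s:e]
        mean_speed = float(np.nanmean(seg)) if np.isfinite(seg).any() else float("nan")
        dist = float("nan")
        if reference is not None:
            steps = np.diff(reference.positions[s:e], axis=0)
            dist = float(np.nansum(np.linalg.norm(steps, axis=1)))
        episodes.append(LocomotionEpisode(FrameInterval(s, e), mean_speed, dist))
    return episodes


def episode_mask(episodes: list[LocomotionEpisode] | list[FrameInterval], n_frames: int) -> np.ndarray:
    """Boolean per-frame mask: True inside any episode."""
    mask = np.zeros(n_frames, dtype=bool)
    for ep in episodes:
        iv = ep.interval if isinstance(ep, LocomotionEpisode) else ep
        mask[iv.start:iv.end] = True
    return mask


def trial_locomotion_summary(
    traj: Trajectory,
    episodes: list[LocomotionEpisode],
    speed: SpeedSeries | None = None,
    frame_rate: float = 300.0,
    bin_s: float = 10.0,
) -> dict:
    """Whole-trial totals: distance travelled, time locomoting, mean speed.

    Distance sums frame-to-frame displacements of the reference point over
    the whole trial; time sums episode durations; mean locomotory speed
    averages the speed series over episode frames only (absent when there are
    none).  Binned outputs use ``bin_s`` bins of the speed series.
    """
    if speed is not None:
        frame_rate = speed.frame_rate
    steps = np.diff(traj.positions, axis=0)
    distance = float(np.nansum(np.linalg.norm(steps, axis=1)))
    time_locomoting = sum(ep.duration_frames for ep in episodes) / frame_rate
    mean_speed = None
    binned = None
    if speed is not None:
        mask = episode_mask(episodes, len(speed.values))
        vals = speed.values[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean_speed = float(vals.mean())
        nb = int(len(speed.values) / (bin_s * frame_rate))
        if nb > 0:
            edges = (np.arange(nb + 1) * bin_s * frame_rate).astype(int)
            binned = [
                float(np.nanmean(speed.values[a:b]))
                if np.isfinite(speed.values[a:b]).any()
                else float("nan")
                for a, b in zip(edges[:-1], edges[1:])
            ]
    return {
        "distance_traveled_mm": distance,
        "time_locomoting_s": float(time_locomoting),
        "mean_locomotory_speed_mm_s": mean_speed,
        "binned_speed_mm_s": binned,
    }


def _belt_axis(surface: dict[str, Trajectory]) -> np.ndarray:
    """Principal horizontal direction of belt-marker motion (unit vector)."""
    vels = []
    for traj in surface.values():
        d = np.diff(traj.positions[:, :2], axis=0)
        d = d[np.isfinite(d).all(axis=1)]
        if len(d):
            vels.append(d)
    if not vels:
        raise ValueError("no observed belt-marker motion to estimate an axis")
    v = np.concatenate(vels)
    cov = v.T @ v
    w, vec = np.linalg.eigh(cov)
    axis2 = vec[:, np.argmax(w)]
    # orient along net displacement so "forward belt motion" is consistent
    if float(v.sum(axis=0) @ axis2) < 0:
        axis2 = -axis2
    return np.array([axis2[0], axis2[1], 0.0])


def _belt_displacement(surface: dict[str, Trajectory], axis: np.ndarray) -> np.ndarray:
    """Cumulative belt translation (mm along axis), averaging visible markers.

    Belt markers cyclically leave and re-enter view (they are spaced 20 cm
    apart on the loop), so per-frame belt velocity is the mean frame-to-frame
    displacement over markers visible in both frames — a natural handoff.
    """
    n = next(iter(surface.values())).n_frames
    num = np.zeros(n - 1)
    cnt = np.zeros(n - 1)
    for traj in surface.values():
        proj = traj.positions @ axis
        d = np.diff(proj)
        ok = np.isfinite(d)
        num[ok] += d[ok]
        cnt[ok] += 1
    vel = np.full(n - 1, np.nan)
    np.divide(num, cnt, out=vel, where=cnt > 0)
    disp = np.concatenate(([0.0], np.nancumsum(vel)))
    disp[np.concatenate(([False], cnt == 0))] = np.nan
    # NaN frames (no visible belt marker) poison subsequent cumsum alignment:
    # carry the last defined value forward but mark frames undefined
    undefined = ~np.isfinite(disp)
    if undefined.any():
        idx = np.arange(n)
        good = ~undefined
        if good.any():
            disp = np.interp(idx, idx[good], disp[good])
        disp[undefined] = np.nan
    return disp


def _wheel_geometry(surface: dict[str, Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Fit the wheel axis (unit vector) and a point on it from rim-marker paths."""
    normals = []
    centers = []
    ref_normal = None
    for traj in surface.values():
        pts = traj.positions[~traj.missing]
        if len(pts) < 10:
            continue
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
        nrm = vt[2]
        if ref_normal is None:
            ref_normal = nrm
        if float(nrm @ ref_normal) < 0:
            nrm = -nrm
        normals.append(nrm)
        # in-plane circle fit (Kasa) for the center
        e1, e2 = vt[0], vt[1]
        u = (pts - c) @ e1
        v = (pts - c) @ e2
        A = np.column_stack([u, v, np.ones_like(u)])
        b = u**2 + v**2
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        uc, vc = sol[0] / 2, sol[1] / 2
        centers.append(c + uc * e1 + vc * e2)
    if not normals:
        raise ValueError("rim markers too sparse to fit the wheel")
    axis = np.mean(normals, axis=0)
    axis /= np.linalg.norm(axis)
    return axis, np.mean(centers, axis=0)


def _rim_angle(surface: dict[str, Trajectory], axis: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Mean unwrapped angular displacement of the rim markers (rad)."""
    # in-plane basis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(float(tmp @ axis)) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    n = next(iter(surface.values())).n_frames
    num = np.zeros(n - 1)
    cnt = np.zeros(n - 1)
    for traj in surface.values():
        rel = traj.positions - center
        ang = np.arctan2(rel @ e2, rel @ e1)
        d = np.diff(ang)
        d = (d + np.pi) % (2 * np.pi) - np.pi
        ok = np.isfinite(d)
        num[ok] += d[ok]
        cnt[ok] += 1
    dang = np.full(n - 1, np.nan)
    np.divide(num, cnt, out=dang, where=cnt > 0)
    theta = np.concatenate(([0.0], np.nancumsum(dang)))
    theta[np.concatenate(([False], cnt == 0))] = np.nan
    undefined = ~np.isfinite(theta)
    if undefined.any():
        idx = np.arange(n)
        good = ~undefined
        theta = np.interp(idx, idx[good], theta[good])
        theta[undefined] = np.nan
    return theta


def surface_relative(trial: TrialRecording) -> TrialRecording:
    """Re-express marker positions relative to the moving substrate.

    TRM: subtract the belt's cumulative translation (common motion of the
    belt markers along the belt axis).  CLB: rotate positions about the
    fitted wheel axis by minus the rim-marker angular displacement.  Frames
    with no visible surface marker are flagged missing in the output.
    """
    if trial.task not in (Task.CLB, Task.TRM):
        raise ValueError("surface correction applies to CLB and TRM tasks only")
    if not trial.surface_markers:
        raise ValueError("trial has no surface markers")
    out = trial.copy()
    if trial.task is Task.TRM:
        axis = _belt_axis(trial.surface_markers)
        disp = _belt_displacement(trial.surface_markers, axis)
        undefined = ~np.isfinite(disp)
        shift = np.where(undefined, 0.0, disp)[:, None] * axis[None, :]
        for traj in out.markers.values():
            traj.positions -= shift
            traj.missing |= undefined
            traj.positions[traj.missing] = np.nan
    else:
        axis, center = _wheel_geometry(trial.surface_markers)
        theta = _rim_angle(trial.surface_markers, axis, center)
        undefined = ~np.isfinite(theta)
        rot = Rotation.from_rotvec(-np.where(undefined, 0.0, theta)[:, None] * axis[None, :])
        for traj in out.markers.values():
            rel = np.where(np.isfinite(traj.positions), traj.positions, 0.0) - center
            traj.positions = rot.apply(rel) + center
            traj.missing |= undefined
            traj.positions[traj.missing] = np.nan
    return out


def head_orientation(
    markers: dict[str, Trajectory],
    front_labels: tuple[str, str] = ("front_l", "front_r"),
    back_labels: tuple[str, str] = ("back_l", "back_r"),
) -> HeadPose:
    """Yaw/pitch/roll of the best-fit headplate plane, frame by frame.

    The forward axis points from the midpoint of the back corner markers to
    the midpoint of the front corner markers, projected into the fitted
    plane; the plane normal is oriented upward.  Angles follow the intrinsic
    z-y'-x'' (yaw-pitch-roll) convention in degrees.  Frames with fewer than
    three visible markers, or a degenerate (collinear) configuration, are NaN.
    """
    if len(markers) < 3:
        raise ValueError("head orientation needs at least 3 markers")
    labs = sorted(markers)
    n = next(iter(markers.values())).n_frames
    yaw = np.full(n, np.nan)
    pitch = np.full(n, np.nan)
    roll = np.full(n, np.nan)
    center = np.full((n, 3), np.nan)
    for i in range(n):
        pts = np.array(
            [markers[lab].positions[i] for lab in labs if not markers[lab].missing[i]]
        )
        if len(pts) < 3:
            continue
        c = pts.mean(axis=0)
        _, sv, vt = np.linalg.svd(pts - c, full_matrices=False)
        if sv[1] < 1e-9 * max(sv[0], 1e-12):  # collinear
            continue
        normal = vt[2]
        if normal[2] < 0:
            normal = -normal
        fm = [
            markers[lab].positions[i]
            for lab in front_labels
            if lab in markers and not markers[lab].missing[i]
        ]
        bm = [
            markers[lab].positions[i]
            for lab in back_labels
            if lab in markers and not markers[lab].missing[i]
        ]
        if not fm or not bm:
            continue
        fwd = np.mean(fm, axis=0) - np.mean(bm, axis=0)
        fwd = fwd - (fwd @ normal) * normal
        norm = np.linalg.norm(fwd)
        if norm < 1e-9:
            continue
        fwd /= norm
        left = np.cross(normal, fwd)
        R = np.column_stack([fwd, left, normal])
        y, p, r = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        yaw[i], pitch[i], roll[i] = y, p, r
        center[i] = c
    return HeadPose(yaw=yaw, pitch=pitch, roll=roll, plane_center=center)
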