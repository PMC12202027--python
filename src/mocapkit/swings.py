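"""Limb-swing detection and per-swing kinematics in three locomotor contexts.

On the treadmill, continuous running yields a quasi-periodic vertical ankle
trajectory and swings are simply the intervals between consecutive vertical
minima.  In the open field and on the climbing wheel, non-locomotor limb
movements make vertical position alone unreliable, so swings are delimited by
the acceleration peak that launches the propulsive phase and the conclusion of
the deceleration phase that ends it, operating on 30-frame (~100 ms) windowed
ankle speeds (surface-relative on the wheel).

Each swing gets the five kinematic measures — duration, mean and maximum
ankle speed, swing height (vertical extent in OF/TRM; amplitude along the
second principal axis of the swing's own 3D point cloud on the wheel, where
body orientation varies), start-to-end Euclidean distance, and 3D path
length — plus the signed timing of the peak ankle speed relative to the
vertical swing peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import FrameInterval, Task, Trajectory
from .locomotion import windowed_speed

__all__ = [
    "SwingEvent",
    "SwingMetrics",
    "detect_swings_treadmill",
    "detect_swings_accel",
    "swing_metrics",
    "timing_summary",
    "DEFAULT_SWING_SPEED_WINDOW_FRAMES",
    "DEFAULT_MIN_PROMINENCE_MM",
]

DEFAULT_SWING_SPEED_WINDOW_FRAMES = 30
DEFAULT_MIN_PROMINENCE_MM = 1.0


@dataclass(frozen=True)
class SwingEvent:
    ankle: str
    interval: FrameInterval
    peak_frame: int  # frame of maximal vertical position within the swing
    context: Task


@dataclass
class SwingMetrics:
    duration_s: float
    mean_speed: float  # mm/s
    max_speed: float  # mm/s
    height: float  # mm
    distance: float  # mm, start-to-end chord
    path_length: float  # mm, summed 3D path
    peak_speed_offset_s: float  # signed, relative to the vertical swing peak
    valid: bool = True


def detect_swings_treadmill(
    ankle: Trajectory,
    frame_rate: float,
    ankle_label: str = "ankle",
    prominence_mm: float = DEFAULT_MIN_PROMINENCE_MM,
    min_separation_frames: int | None = None,
    stride_frequency_hz: float | None = None,
) -> list[SwingEvent]:
    """Delimit swings at consecutive minima of the vertical ankle trajectory.

    Minima are local minima of z with at least ``prominence_mm`` prominence
    (suppressing tremor-scale ripples) separated by at least
    ``min_separation_frames`` (default half a stride period when a stride
    frequency estimate is given, else ~50 ms).  Fewer than two minima yield
    no swings.  The ankle trajectory should already be surface-relative and
    gap-filled.
    """
    z = ankle.z
    if min_separation_frames is None:
        if stride_frequency_hz:
            min_separation_frames = max(int(0.5 * frame_rate / stride_frequency_hz), 1)
        else:
            min_separation_frames = max(int(0.05 * frame_rate), 1)
    zi = z.copy()
    bad = ~np.isfinite(zi)
    if bad.any():
        idx = np.arange(len(zi))
        if (~bad).sum() < 2:
            return []
        zi = np.interp(idx, idx[~bad], zi[~bad])
    minima, _ = find_peaks(-zi, prominence=prominence_mm, distance=min_separation_frames)
    if len(minima) < 2:
        return []
    events = []
    for s, e in zip(minima[:-1], minima[1:]):
        peak = int(s + np.nanargmax(z[s:e + 1]))
        events.append(SwingEvent(ankle_label, FrameInterval(int(s), int(e) + 1), peak, Task.TRM))
    return events


def _local_maxima(values: np.ndarray, prominence: float | None = None) -> np.ndarray:
    peaks, _ = find_peaks(values, prominence=prominence)
    return peaks


def detect_swings_accel(
    ankle: Trajectory,
    frame_rate: float,
    context: Task = Task.OF,
    ankle_label: str = "ankle",
    window_frames: int = DEFAULT_SWING_SPEED_WINDOW_FRAMES,
    speed_threshold_mm_s: float | None = None,
) -> list[SwingEvent]:
    """Delimit swings by acceleration/deceleration peaks flanking fast motion.

    3D windowed ankle speed is computed over ``window_frames``; candidate
    segments are runs where it exceeds an adaptive threshold (mean + 1 SD of
    the defined speed samples unless an explicit threshold is given).  Each
    candidate extends backward to the nearest preceding acceleration peak
    (the propulsive launch) and forward to the conclusion of the deceleration
    phase — the first frame after the deceleration peak where the
    deceleration has died off (acceleration back at/above zero) or the speed
    bottoms out.  Overlapping candidates merge into one swing.
    """
    speed = windowed_speed(ankle, window_frames, frame_rate).values
    defined = np.isfinite(speed)
    if defined.sum() < 3:
        return []
    if speed_threshold_mm_s is None:
        mu = float(speed[defined].mean())
        sd = float(speed[defined].std())
        speed_threshold_mm_s = mu + sd
    above = np.zeros(len(speed), dtype=bool)
    above[defined] = speed[defined] > speed_threshold_mm_s
    if not above.any():
        return []
    accel = np.gradient(np.where(defined, speed, np.nan))
    # light smoothing plus a prominence filter keep the launch/brake peaks
    # and drop noise ripples
    k = max(int(round(window_frames / 4)) | 1, 3)
    kern = np.ones(k) / k
    finite = np.isfinite(accel)
    accel_s = np.convolve(np.where(finite, accel, 0.0), kern, mode="same")
    norm = np.convolve(finite.astype(float), kern, mode="same")
    accel_s = np.where(norm > 0, accel_s / np.maximum(norm, 1e-12), np.nan)
    accel_s[~finite] = np.nan
    acc_prom = float(np.nanstd(accel_s)) if finite.any() else None
    acc_peaks = _local_maxima(np.nan_to_num(accel_s, nan=-np.inf), acc_prom)
    dec_peaks = _local_maxima(np.nan_to_num(-accel_s, nan=-np.inf), acc_prom)
    accel = accel_s

    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)

    intervals: list[tuple[int, int]] = []
    n = len(speed)
    for s, e in zip(starts, ends):
        # anchor at the run's speed maximum: the launching acceleration peak
        # precedes it and the braking deceleration peak follows it
        seg = np.where(defined[s:e], speed[s:e], -np.inf)
        apex = s + int(np.argmax(seg))
        prev = acc_peaks[acc_peaks <= apex]
        start = int(prev[-1]) if len(prev) else int(s)
        nxt = dec_peaks[dec_peaks >= apex]
        if len(nxt):
            dp = int(nxt[0])
            # deceleration "concludes" once braking has decayed to 10 % of
            # its peak (a threshold comfortably above the noise floor)
            resid = 0.1 * (-accel[dp])
            end = dp
            while end + 1 < n and np.isfinite(accel[end + 1]) and accel[end + 1] < -resid:
                end += 1
            end = min(end + 1, n)
        else:
            end = int(e)
        if end <= start:
            continue
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    events = []
    z = ankle.z
    for s, e in intervals:
        seg = z[s:e]
        if not np.isfinite(seg).any():
            continue
        peak = int(s + np.nanargmax(seg))
        events.append(SwingEvent(ankle_label, FrameInterval(s, e), peak, context))
    return events


def swing_metrics(
    event: SwingEvent,
    ankle: Trajectory,
    frame_rate: float,
    context: Task | None = None,
) -> SwingMetrics:
    """The five per-swing kinematic measures plus peak-speed timing.

    Frame-wise speeds are instantaneous (frame-to-frame displacement times
    frame rate).  Swings containing missing or gap-filled frames are returned
    with ``valid=False`` and NaN measures — interpolated sections are good
    enough for continuity but not for kinematic feature claims.
    """
    context = context or event.context
    s, e = event.interval.start, event.interval.end
    pos = ankle.positions[s:e]
    contaminated = bool(ankle.missing[s:e].any() or ankle.filled[s:e].any())
    if contaminated or len(pos) < 2:
        nan = float("nan")
        return SwingMetrics(nan, nan, nan, nan, nan, nan, nan, valid=False)
    steps = np.diff(pos, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    frame_speeds = step_len * frame_rate
    duration = (e - s) / frame_rate
    distance = float(np.linalg.norm(pos[-1] - pos[0]))
    path_length = float(step_len.sum())
    if context is Task.CLB:
        centered = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[1]
        height = float(scores.max() - scores.min())
    else:
        height = float(pos[:, 2].max() - pos[:, 2].min())
    # frame_speeds[i] spans frames s+i -> s+i+1; attribute it to s+i
    peak_speed_frame = s + int(np.argmax(frame_speeds))
    offset = (peak_speed_frame - event.peak_frame) / frame_rate
    return SwingMetrics(
        duration_s=float(duration),
        mean_speed=float(frame_speeds.mean()),
        max_speed=float(frame_speeds.max()),
        height=height,
        distance=distance,
        path_length=path_length,
        peak_speed_offset_s=float(offset),
    )


def timing_summary(metrics: list[SwingMetrics]) -> dict:
    """Distribution of signed peak-speed offsets over valid swings."""
    offsets = np.array([m.peak_speed_offset_s for m in metrics if m.valid])
    if offsets.size == 0:
        raise ValueError("no valid swings")
    return {
        "offsets_s": offsets,
        "median_s": float(np.percentile(offsets, 50)),
        "q25_s": float(np.percentile(offsets, 25)),
        "q75_s": float(np.percentile(offsets, 75)),
        "n": int(offsets.size),
    }
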