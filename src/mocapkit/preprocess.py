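"""Trajectory repair: gap detection, short-gap interpolation, jitter removal.

Markers occasionally drop out (occlusion) leaving runs of missing frames, and
reconstruction ambiguity can produce transient sub-millimetre "glitches".
The repair policy is deliberately minimal: short interior gaps (strictly
shorter than 50 frames at 300 fps, ~165 ms) are bridged by per-axis linear
interpolation so that windowed computations stay defined; longer or
boundary-touching gaps stay missing.  Jitter events — localized deviations
exceeding 0.05 mm in peak prominence lasting no more than three frames — are
excised together with their immediate neighbours and replaced by linear
interpolation.  Observed samples outside events are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import FrameInterval, Trajectory, TrialRecording

__all__ = [
    "GapRecord",
    "JitterEvent",
    "find_gaps",
    "fill_short_gaps",
    "remove_jitter",
    "clean_trial",
    "DEFAULT_MAX_GAP_FRAMES",
    "DEFAULT_JITTER_PROMINENCE_MM",
    "DEFAULT_JITTER_MAX_WIDTH_FRAMES",
]

DEFAULT_MAX_GAP_FRAMES = 50
DEFAULT_JITTER_PROMINENCE_MM = 0.05
DEFAULT_JITTER_MAX_WIDTH_FRAMES = 3


@dataclass(frozen=True)
class GapRecord:
    """A maximal run of missing frames in one marker trajectory."""

    marker: str
    interval: FrameInterval
    filled: bool = False

    @property
    def duration_frames(self) -> int:
        return self.interval.duration


@dataclass(frozen=True)
class JitterEvent:
    """A transient spurious deviation detected on one axis of a marker."""

    marker: str
    axis: str  # "x", "y" or "z"
    frame: int  # index of the peak deviation
    width_frames: int
    prominence: float  # mm


def find_gaps(traj: Trajectory, marker: str = "") -> list[GapRecord]:
    """Report every maximal run of missing frames as one gap."""
    m = traj.missing
    if not m.any():
        return []
    padded = np.concatenate(([False], m, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [GapRecord(marker, FrameInterval(int(s), int(e))) for s, e in zip(starts, ends)]


def fill_short_gaps(
    traj: Trajectory,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    marker: str = "",
) -> tuple[Trajectory, list[GapRecord]]:
    """Bridge interior gaps strictly shorter than ``max_gap_frames``.

    Filling is per-axis linear interpolation between the flanking observed
    frames.  Gaps at the trial boundaries (no flanking sample on one side) and
    gaps of ``max_gap_frames`` or longer are left missing.  Filled frames are
    flagged in the returned trajectory's ``filled`` mask so that event-level
    kinematic measures can exclude them.
    """
    if max_gap_frames < 1:
        raise ValueError("max_gap_frames must be >= 1")
    out = traj.copy()
    n = len(out)
    records: list[GapRecord] = []
    for gap in find_gaps(traj, marker):
        s, e = gap.interval.start, gap.interval.end
        interior = s > 0 and e < n
        fillable = interior and gap.duration_frames < max_gap_frames
        if fillable:
            left = out.positions[s - 1]
            right = out.positions[e]
            frac = (np.arange(s, e) - (s - 1)) / (e - (s - 1))
            out.positions[s:e] = left + frac[:, None] * (right - left)
            out.missing[s:e] = False
            out.filled[s:e] = True
        records.append(GapRecord(gap.marker, gap.interval, filled=fillable))
    return out, records


def _jitter_events_one_axis(
    values: np.ndarray,
    observed: np.ndarray,
    prominence_mm: float,
    max_width_frames: int,
) -> list[tuple[int, int, int, float]]:
    """Candidate (start, end, peak, prominence) spans on one axis.

    A candidate is a local extremum of prominence above threshold whose
    deviation from the straight line between its flanking bases persists for
    no more than ``max_width_frames`` consecutive frames.  Spans touching
    missing data or the signal boundary are skipped (gap handling wins).
    """
    events = []
    n = len(values)
    v = values.copy()
    # neutralize missing stretches so find_peaks sees finite data; events
    # overlapping them are discarded below
    if (~observed).any():
        idx = np.arange(n)
        if observed.sum() < 2:
            return []
        v = np.interp(idx, idx[observed], values[observed])
    for sign in (1.0, -1.0):
        peaks, props = find_peaks(sign * v, prominence=prominence_mm)
        for k, p in enumerate(peaks):
            lb = int(props["left_bases"][k])
            rb = int(props["right_bases"][k])
            prom = float(props["prominences"][k])
            # deviation from the chord between the bases
            span = np.arange(lb, rb + 1)
            chord = v[lb] + (v[rb] - v[lb]) * (span - lb) / max(rb - lb, 1)
            dev = sign * (v[span] - chord)
            above = dev > prom / 2
            # contiguous run containing the peak
            pi = p - lb
            if not above[pi]:
                continue
            s = pi
            while s > 0 and above[s - 1]:
                s -= 1
            e = pi
            while e < len(above) - 1 and above[e + 1]:
                e += 1
            start, end = lb + s, lb + e + 1
            width = end - start
            if width > max_width_frames:
                continue
            if start < 1 or end > n - 2:  # need observed neighbours on both sides
                continue
            if not observed[max(start - 1, 0):min(end + 1, n)].all():
                continue
            events.append((start, end, int(p), prom))
    return events


def remove_jitter(
    traj: Trajectory,
    prominence_mm: float = DEFAULT_JITTER_PROMINENCE_MM,
    max_width_frames: int = DEFAULT_JITTER_MAX_WIDTH_FRAMES,
    marker: str = "",
    max_passes: int = 5,
) -> tuple[Trajectory, list[JitterEvent]]:
    """Detect and excise transient jitter events, axis by axis.

    Event frames and their immediate neighbours are replaced by linear
    interpolation across the excised span.  Detection and repair iterate to
    convergence (bounded by ``max_passes``), which makes the operation
    idempotent; on clean data one pass suffices.  The missing mask and length
    are preserved.
    """
    if prominence_mm <= 0 or max_width_frames <= 0:
        raise ValueError("thresholds must be positive")
    out = traj.copy()
    observed = ~out.missing
    all_events: list[JitterEvent] = []
    axis_names = ("x", "y", "z")
    for _ in range(max_passes):
        pass_events: list[JitterEvent] = []
        for ax in range(3):
            vals = out.positions[:, ax]
            cands = _jitter_events_one_axis(
                np.where(observed, vals, np.nan), observed, prominence_mm, max_width_frames
            )
            for start, end, peak, prom in cands:
                # excise the event plus one neighbour each side
                lo, hi = start - 1, end + 1  # interpolate from lo to hi inclusive ends
                span = np.arange(lo + 1, hi)
                frac = (span - lo) / (hi - lo)
                out.positions[span, ax] = vals[lo] + frac * (vals[hi] - vals[lo])
                pass_events.append(
                    JitterEvent(marker, axis_names[ax], peak, end - start, prom)
                )
        if not pass_events:
            break
        all_events.extend(pass_events)
    return out, all_events


def clean_trial(
    trial: TrialRecording,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
    jitter_prominence_mm: float = DEFAULT_JITTER_PROMINENCE_MM,
    jitter_max_width_frames: int = DEFAULT_JITTER_MAX_WIDTH_FRAMES,
) -> tuple[TrialRecording, dict[str, list[GapRecord]], dict[str, list[JitterEvent]]]:
    """Apply gap filling then jitter removal to every trajectory of a trial."""
    out = trial.copy()
    gaps: dict[str, list[GapRecord]] = {}
    jitters: dict[str, list[JitterEvent]] = {}
    for group in (out.markers, out.surface_markers):
        for lab, traj in group.items():
            filled, grecs = fill_short_gaps(traj, max_gap_frames, marker=lab)
            repaired, jrecs = remove_jitter(
                filled, jitter_prominence_mm, jitter_max_width_frames, marker=lab
            )
            group[lab] = repaired
            gaps[lab] = grecs
            jitters[lab] = jrecs
    return out, gaps, jitters
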