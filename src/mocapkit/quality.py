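"""Tracking-quality quantification: visibility, gaps, residuals, accuracy maps.

Three complementary views of capture performance: robustness (how often each
marker is seen, and how long the drop-outs last), precision (triangulation
residuals reported by the capture software, consumed here as input), and
accuracy (frame-by-frame deviation of measured inter-marker distances from the
known implant spacing; assuming both markers contribute equally, half the
pairwise error is attributed to each marker).  Summaries are split by
behavioural state (locomotory vs stationary); spatial maps bin a per-frame
metric over the arena using the hip-midpoint as reference position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TrialRecording
from .locomotion import LocomotionEpisode, episode_mask
from .preprocess import GapRecord

__all__ = [
    "QualityReport",
    "SpatialMap",
    "marker_visibility",
    "pairwise_distance_error",
    "residual_summary",
    "gap_duration_distribution",
    "spatial_map",
    "quality_report",
    "ecdf",
]


@dataclass
class SpatialMap:
    """Per-bin mean of a metric over the arena; empty bins are NaN, not zero."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # (nx, ny)
    counts: np.ndarray  # samples per bin


@dataclass
class QualityReport:
    per_frame_visible_fraction: np.ndarray
    per_marker_visibility_pct: dict[str, float]
    gap_durations_by_state: dict[str, list[int]]
    residual_summary_by_state: dict[str, dict[str, float]] | None
    pairwise_error_by_state: dict[str, dict[str, float]] | None
    visible_fraction_p05: float


def marker_visibility(trial: TrialRecording) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame fraction of visible markers and per-marker visibility (%)."""
    if not trial.markers:
        raise ValueError("trial has no markers")
    masks = np.array([~t.missing for t in trial.markers.values()])
    frac = masks.mean(axis=0)
    pct = {
        lab: 100.0 * float((~t.missing).mean()) for lab, t in trial.markers.items()
    }
    return frac, pct


def pairwise_distance_error(
    trial: TrialRecording,
) -> tuple[dict[tuple[str, str], np.ndarray], dict[str, np.ndarray]]:
    """|measured inter-marker distance - known distance| per pair and frame.

    Frames where either marker is missing are NaN.  The per-marker error is
    half the pairwise error (both markers assumed to contribute equally);
    markers in several pairs average their halves.
    """
    if not trial.known_pairs:
        raise ValueError("trial has no known marker pairs")
    n = trial.n_frames
    per_pair: dict[tuple[str, str], np.ndarray] = {}
    acc: dict[str, list[np.ndarray]] = {}
    for pair in trial.known_pairs:
        a = trial.markers[pair.label_a]
        b = trial.markers[pair.label_b]
        d = np.linalg.norm(a.positions - b.positions, axis=1)
        err = np.abs(d - pair.known_distance)
        err[a.missing | b.missing] = np.nan
        per_pair[(pair.label_a, pair.label_b)] = err
        for lab in (pair.label_a, pair.label_b):
            acc.setdefault(lab, []).append(err / 2.0)
    per_marker = {
        lab: np.nanmean(np.array(series), axis=0) if len(series) > 1 else series[0]
        for lab, series in acc.items()
    }
    return per_pair, per_marker


def _state_summary(values: np.ndarray, loco: np.ndarray) -> dict[str, dict[str, float]]:
    out = {}
    for state, mask in (("locomotory", loco), ("stationary", ~loco)):
        v = values[mask]
        v = v[np.isfinite(v)]
        if v.size:
            out[state] = {
                "median_mm": float(np.percentile(v, 50)),
                "p95_mm": float(np.percentile(v, 95)),
                "n": int(v.size),
            }
        else:
            out[state] = {"median_mm": float("nan"), "p95_mm": float("nan"), "n": 0}
    return out


def residual_summary(
    trial: TrialRecording, episodes: list[LocomotionEpisode]
) -> dict[str, dict[str, float]] | None:
    """Median / 95th-percentile triangulation residual per behavioural state.

    Frames and markers are pooled.  Returns None (an explicit "not
    available") when the trial carries no residuals.
    """
    if not trial.residuals:
        return None
    n = trial.n_frames
    loco = episode_mask(episodes, n)
    pooled = np.concatenate([np.asarray(r, dtype=float) for r in trial.residuals.values()])
    states = np.concatenate([loco for _ in trial.residuals])
    return _state_summary(pooled, states)


def pairwise_error_summary(
    trial: TrialRecording, episodes: list[LocomotionEpisode]
) -> dict[str, dict[str, float]] | None:
    if not trial.known_pairs:
        return None
    per_pair, _ = pairwise_distance_error(trial)
    loco = episode_mask(episodes, trial.n_frames)
    pooled = np.concatenate(list(per_pair.values()))
    states = np.concatenate([loco for _ in per_pair])
    return _state_summary(pooled, states)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return v, v
    p = np.arange(1, v.size + 1) / v.size
    return v, p


def gap_duration_distribution(
    gaps: list[GapRecord],
    episodes: list[LocomotionEpisode],
    n_frames: int,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-state gap-duration samples and empirical CDFs.

    A gap is assigned to the state of its start frame (locomotory if that
    frame lies inside an episode).
    """
    loco = episode_mask(episodes, n_frames)
    durations: dict[str, list[int]] = {"locomotory": [], "stationary": []}
    for g in gaps:
        state = "locomotory" if loco[g.interval.start] else "stationary"
        durations[state].append(g.duration_frames)
    out = {}
    for state, dur in durations.items():
        x, p = ecdf(np.array(dur, dtype=float))
        out[state] = {"durations": np.array(dur), "x": x, "cdf": p}
    return out


def spatial_map(
    metric_series: np.ndarray,
    reference_xy: np.ndarray,
    n_bins: int = 20,
    smooth_frames: int | None = None,
) -> SpatialMap:
    """Bin a per-frame metric over the arena by reference position.

    ``smooth_frames`` applies a centered moving average to the metric first
    (the missing-marker-count map uses a 100-frame, ~300 ms window).
    """
    metric = np.asarray(metric_series, dtype=float)
    xy = np.asarray(reference_xy, dtype=float)
    if len(metric) != len(xy):
        raise ValueError("metric and reference series must have equal length")
    if smooth_frames:
        kernel = np.ones(smooth_frames) / smooth_frames
        finite = np.isfinite(metric)
        vals = np.where(finite, metric, 0.0)
        num = np.convolve(vals, kernel, mode="same")
        den = np.convolve(finite.astype(float), kernel, mode="same")
        metric = np.where(den > 0, num / den, np.nan)
    ok = np.isfinite(metric) & np.isfinite(xy).all(axis=1)
    x_edges = np.linspace(np.nanmin(xy[:, 0]), np.nanmax(xy[:, 0]), n_bins + 1)
    y_edges = np.linspace(np.nanmin(xy[:, 1]), np.nanmax(xy[:, 1]), n_bins + 1)
    sums, _, _ = np.histogram2d(
        xy[ok, 0], xy[ok, 1], bins=[x_edges, y_edges], weights=metric[ok]
    )
    counts, _, _ = np.histogram2d(xy[ok, 0], xy[ok, 1], bins=[x_edges, y_edges])
    values = np.full_like(sums, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    return SpatialMap(x_edges=x_edges, y_edges=y_edges, values=values, counts=counts)


def quality_report(
    trial: TrialRecording,
    gaps: list[GapRecord],
    episodes: list[LocomotionEpisode],
) -> QualityReport:
    frac, pct = marker_visibility(trial)
    gap_dist = gap_duration_distribution(gaps, episodes, trial.n_frames)
    return QualityReport(
        per_frame_visible_fraction=frac,
        per_marker_visibility_pct=pct,
        gap_durations_by_state={
            s: [int(d) for d in v["durations"]] for s, v in gap_dist.items()
        },
        residual_summary_by_state=residual_summary(trial, episodes),
        pairwise_error_by_state=pairwise_error_summary(trial, episodes),
        visible_fraction_p05=float(np.percentile(frac, 5)),
    )
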