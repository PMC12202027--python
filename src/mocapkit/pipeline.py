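"""End-to-end pipeline driver: clean -> qc -> locomotion -> mi -> swings -> tremor.

One :class:`PipelineConfig` gathers every stage threshold with the
standard defaults; the full configuration is echoed into every report for
provenance, and identical input plus configuration always produces
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import locomotion as loco
from . import motion_index as mi_mod
from . import preprocess as pre
from . import quality as qual
from . import swings as sw
from . import tremor as trem
from .io import FrameInterval, Task, Trajectory, TrialRecording

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("mocapkit")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every stage threshold, defaulting to the standard study-scale values."""

    max_gap_frames: int = pre.DEFAULT_MAX_GAP_FRAMES  # fill gaps strictly shorter
    jitter_prominence_mm: float = pre.DEFAULT_JITTER_PROMINENCE_MM
    jitter_max_width_frames: int = pre.DEFAULT_JITTER_MAX_WIDTH_FRAMES
    episode_threshold_mm_s: float = loco.DEFAULT_SPEED_THRESHOLD_MM_S
    episode_min_frames: int = loco.DEFAULT_MIN_EPISODE_FRAMES
    episode_max_dip_frames: int = loco.DEFAULT_MAX_DIP_FRAMES
    onset_speed_window_frames: int = loco.DEFAULT_ONSET_WINDOW_FRAMES  # ~300 ms
    report_speed_window_s: float = 1.0
    mi_window_frames: int = mi_mod.DEFAULT_MI_WINDOW_FRAMES
    mi_dims: int = 3
    swing_speed_window_frames: int = sw.DEFAULT_SWING_SPEED_WINDOW_FRAMES
    swing_min_prominence_mm: float = sw.DEFAULT_MIN_PROMINENCE_MM
    tremor_band_hz: tuple[float, float] = trem.DEFAULT_BAND_HZ
    tremor_derivative_threshold: float = trem.DEFAULT_DERIVATIVE_THRESHOLD
    tremor_amplitude_window_frames: int = trem.DEFAULT_AMPLITUDE_WINDOW_FRAMES
    movement_split_mm_s: float = trem.DEFAULT_MOVEMENT_SPLIT_MM_S
    hip_labels: tuple[str, str] = loco.HIP_LABELS
    ankle_labels: tuple[str, ...] = ("ankle_l", "ankle_r")
    run_tremor: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tremor_band_hz"] = list(self.tremor_band_hz)
        d["hip_labels"] = list(self.hip_labels)
        d["ankle_labels"] = list(self.ankle_labels)
        return d


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default,
                  allow_nan=True)
        fh.write("\n")


def run_pipeline(
    trial: TrialRecording,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run all stages applicable to the trial's task and assemble a report.

    Returns the report dict; when ``out_dir`` is given, one JSON file per
    stage is written there together with a run log.  Stage failures raise
    :class:`PipelineError` after preserving partial outputs.
    """
    config = config or PipelineConfig()
    report: dict = {"trial_id": trial.trial_id, "task": trial.task.value,
                    "config": config.to_dict()}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: list[str] = []

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            timings.append(f"{name}: FAILED ({exc})")
            if out is not None:
                _dump(report, out / "report.json")
                (out / "run.log").write_text("\n".join(timings) + "\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        report[name] = result
        timings.append(f"{name}: {time.perf_counter() - t0:.3f} s")
        if out is not None:
            _dump(result, out / f"{name}.json")
        return result

    # --- clean ---------------------------------------------------------
    def _clean():
        cleaned, gaps, jitters = pre.clean_trial(
            trial, config.max_gap_frames, config.jitter_prominence_mm,
            config.jitter_max_width_frames,
        )
        state["trial"] = cleaned
        state["gaps"] = [g for recs in gaps.values() for g in recs]
        return {
            "n_gaps": sum(len(v) for v in gaps.values()),
            "n_gaps_filled": sum(g.filled for v in gaps.values() for g in v),
            "n_jitter_events": sum(len(v) for v in jitters.values()),
            "gaps": {k: v for k, v in gaps.items() if v},
            "jitter": {k: v for k, v in jitters.items() if v},
        }

    state: dict = {}
    _stage("clean", _clean)
    cleaned: TrialRecording = state["trial"]

    # --- surface correction + locomotion -------------------------------
    def _locomotion():
        work = cleaned
        if cleaned.task in (Task.CLB, Task.TRM):
            if not cleaned.surface_markers:
                raise ValueError(f"{cleaned.task.value} trial lacks surface markers")
            work = loco.surface_relative(cleaned)
        state["work"] = work
        ref = loco.hip_midpoint(work, config.hip_labels)
        state["ref"] = ref
        onset_speed = loco.windowed_speed(ref, config.onset_speed_window_frames,
                                          work.frame_rate)
        episodes = loco.detect_locomotion_episodes(
            onset_speed, config.episode_threshold_mm_s, config.episode_min_frames,
            config.episode_max_dip_frames, reference=ref,
        )
        state["episodes"] = episodes
        report_speed = loco.windowed_speed(
            ref, int(config.report_speed_window_s * work.frame_rate), work.frame_rate
        )
        summary = loco.trial_locomotion_summary(ref, episodes, report_speed)
        return {
            "episodes": [
                {"start": ep.interval.start, "end": ep.interval.end,
                 "mean_speed_mm_s": ep.mean_speed, "distance_mm": ep.distance}
                for ep in episodes
            ],
            **summary,
        }

    _stage("locomotion", _locomotion)

    # --- qc -------------------------------------------------------------
    def _qc():
        rep = qual.quality_report(trial, state["gaps"], state["episodes"])
        return {
            "per_marker_visibility_pct": rep.per_marker_visibility_pct,
            "visible_fraction_p05": rep.visible_fraction_p05,
            "gap_durations_by_state": rep.gap_durations_by_state,
            "residual_summary_by_state": rep.residual_summary_by_state,
            "pairwise_error_by_state": rep.pairwise_error_by_state,
        }

    _stage("qc", _qc)

    # --- mi -------------------------------------------------------------
    def _mi():
        res = mi_mod.motion_index(
            state["work"], state["episodes"], config.mi_window_frames, config.mi_dims
        )
        return {
            "mean_mi_locomotory_mm_s": res.mean_mi_locomotory,
            "mean_mi_stationary_mm_s": res.mean_mi_stationary,
            "binned_means_mm_s": res.binned_means,
            "mean_stationary_displacement_mm": (
                float(res.stationary_displacements.mean())
                if res.stationary_displacements.size else None
            ),
        }

    _stage("mi", _mi)

    # --- swings ---------------------------------------------------------
    def _swings():
        work = state["work"]
        rows = []
        for lab in config.ankle_labels:
            if lab not in work.markers:
                continue
            ankle = work.markers[lab]
            if work.task is Task.TRM:
                # minima-based delimitation assumes continuous running, so
                # detect within locomotory episodes only
                events = []
                for ep in state["episodes"]:
                    seg = Trajectory(
                        ankle.positions[ep.interval.to_slice()],
                        ankle.missing[ep.interval.to_slice()],
                        ankle.filled[ep.interval.to_slice()],
                    )
                    for ev in sw.detect_swings_treadmill(
                        seg, work.frame_rate, lab,
                        prominence_mm=config.swing_min_prominence_mm,
                    ):
                        events.append(sw.SwingEvent(
                            lab,
                            FrameInterval(ev.interval.start + ep.interval.start,
                                          ev.interval.end + ep.interval.start),
                            ev.peak_frame + ep.interval.start,
                            ev.context,
                        ))
            else:
                events = sw.detect_swings_accel(
                    ankle, work.frame_rate, work.task, lab,
                    window_frames=config.swing_speed_window_frames,
                )
            for ev in events:
                m = sw.swing_metrics(ev, ankle, work.frame_rate)
                rows.append({"ankle": lab, "start": ev.interval.start,
                             "end": ev.interval.end, **dataclasses.asdict(m)})
        valid = [r for r in rows if r["valid"]]
        summary = None
        if valid:
            offsets = np.array([r["peak_speed_offset_s"] for r in valid])
            summary = {
                "n_swings": len(valid),
                "median_peak_speed_offset_s": float(np.median(offsets)),
                "mean_height_mm": float(np.mean([r["height"] for r in valid])),
                "mean_duration_s": float(np.mean([r["duration_s"] for r in valid])),
            }
        return {"events": rows, "summary": summary}

    _stage("swings", _swings)

    # --- tremor ---------------------------------------------------------
    if config.run_tremor:
        def _tremor():
            work = state["work"]
            analyzable = [
                lab for lab, t in work.markers.items() if not t.missing.any()
            ]
            if not analyzable:
                return {"note": "no gap-free markers to analyze"}
            summary = trem.tremor_summary(
                work, state["episodes"], markers=analyzable,
                movement_split_mm_s=config.movement_split_mm_s,
                amplitude_window_frames=config.tremor_amplitude_window_frames,
            )
            profiles = summary.pop("profiles")
            summary["per_axis_profiles"] = [
                {"marker": p.marker, "axis": p.axis, "band_hz": p.band,
                 "peak_frequency_hz": p.peak_frequency,
                 "mean_amplitude_mm": p.mean_amplitude}
                for p in profiles
            ]
            return summary

        _stage("tremor", _tremor)

    if out is not None:
        _dump(report, out / "report.json")
        (out / "run.log").write_text("\n".join(timings) + "\n")
    return report
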