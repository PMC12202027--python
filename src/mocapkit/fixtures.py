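"""Deterministic fixture builder: tiny trials with exactly known outputs.

Every fixture is regenerated programmatically (nothing is stored), small
enough to eyeball as TSV/JSON, and tagged with how its expected values were
obtained: constructed arithmetic (trivial) or an independent oracle scripted
in the test suite (derived).  ``build_fixtures`` writes the set to a
directory and is byte-stable for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .io import MarkerPairSpec, Task, Trajectory, TrialRecording, write_metadata, write_trial
from .synthetic import (
    BreathingModel,
    EpisodeModel,
    GaitModel,
    GapModel,
    GlitchModel,
    SyntheticConfig,
    TremorModel,
    generate_trial,
)

__all__ = [
    "static_pair_trial",
    "spike_trajectory",
    "gap_trajectory",
    "semicircle_arc",
    "tremor_trial_config",
    "gait_trial_config",
    "build_fixtures",
]


def static_pair_trial(n_frames: int = 200, separation_mm: float = 14.0) -> TrialRecording:
    """Two motionless markers at an exactly known separation (pair error 0)."""
    a = np.tile([0.0, 0.0, 30.0], (n_frames, 1))
    b = np.tile([0.0, separation_mm, 30.0], (n_frames, 1))
    return TrialRecording(
        trial_id="static-pair",
        task=Task.OF,
        markers={
            "hip_l": Trajectory.from_positions(a),
            "hip_r": Trajectory.from_positions(b),
        },
        frame_rate=300.0,
        known_pairs=[MarkerPairSpec("hip_l", "hip_r", separation_mm)],
    )


def spike_trajectory(
    n_frames: int = 100,
    spike_frame: int = 50,
    amplitude_mm: float = 0.1,
    width_frames: int = 1,
) -> Trajectory:
    """Flat baseline with a rectangular z-spike of known position and size."""
    pos = np.tile([10.0, 20.0, 30.0], (n_frames, 1))
    pos[spike_frame:spike_frame + width_frames, 2] += amplitude_mm
    return Trajectory.from_positions(pos)


def gap_trajectory(n_frames: int = 60, gap_start: int = 10, gap_len: int = 11) -> Trajectory:
    """Linear motion with one missing run: the exact fill is the line itself."""
    t = np.arange(n_frames, dtype=float)
    pos = np.column_stack([t, np.zeros(n_frames), 0.4 * t])
    missing = np.zeros(n_frames, dtype=bool)
    missing[gap_start:gap_start + gap_len] = True
    return Trajectory(pos, missing)


def semicircle_arc(radius_mm: float = 10.0, n_frames: int = 181) -> np.ndarray:
    """Vertical-plane semicircular arc: chord 2r, path pi*r, height r."""
    theta = np.linspace(np.pi, 0.0, n_frames)
    return np.column_stack(
        [radius_mm * np.cos(theta) + radius_mm,
         np.zeros(n_frames),
         radius_mm * np.sin(theta)]
    )


def tremor_trial_config(
    seed: int = 0,
    duration_s: float = 40.0,
    frequency_hz: float = 10.0,
    amplitude_mm: float = 0.5,
    phase_offsets: dict[str, float] | None = None,
    noise_sd_mm: float = 0.02,
) -> SyntheticConfig:
    """An immobile, tremoring mouse (the drug-induced tremor scenario)."""
    return SyntheticConfig(
        seed=seed,
        duration_s=duration_s,
        task=Task.OF,
        episode_model=EpisodeModel(enabled=False),
        gait_model=GaitModel(enabled=False),
        tremor_model=TremorModel(
            enabled=True,
            frequency_hz=frequency_hz,
            amplitude_mm=amplitude_mm,
            phase_offsets_rad=phase_offsets or {},
        ),
        breathing_model=BreathingModel(enabled=False),
        noise_sd_mm=noise_sd_mm,
    )


def gait_trial_config(
    seed: int = 0,
    task: Task = Task.TRM,
    duration_s: float = 20.0,
    noise_sd_mm: float = 0.01,
) -> SyntheticConfig:
    """Continuous locomotion with ankle stride cycles (>=10 strides)."""
    return SyntheticConfig(
        seed=seed,
        duration_s=duration_s,
        task=task,
        episode_model=EpisodeModel(mean_episode_s=8.0, mean_pause_s=1.0),
        gait_model=GaitModel(enabled=True),
        breathing_model=BreathingModel(enabled=False),
        noise_sd_mm=noise_sd_mm,
    )


def build_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Regenerate the fixture directory deterministically (TSV/JSON only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial = static_pair_trial()
    write_trial(trial, out / "static_pair.tsv")
    write_metadata(trial, out / "static_pair.meta.yaml")

    synth, truth = generate_trial(gait_trial_config(seed=seed, duration_s=10.0))
    write_trial(synth, out / "gait_trm.tsv")
    write_metadata(synth, out / "gait_trm.meta.yaml")
    manifest = {
        "static_pair": {
            "provenance": "trivial",
            "expected": {"pairwise_error_mm": 0.0, "visibility_pct": 100.0},
        },
        "gait_trm": {
            "provenance": "derived (generator ground truth)",
            "expected": {
                "n_swings_left": len(truth.swings["ankle_l"]),
                "n_swings_right": len(truth.swings["ankle_r"]),
                "swing_height_mm": 10.0,
            },
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
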