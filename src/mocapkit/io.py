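"""Core domain types and a plain-text trajectory exchange format.

A trial is one motion-capture recording: a set of labelled 3D marker
trajectories sampled at a fixed frame rate, with per-frame missing flags
(occluded or untracked markers), optional surface markers (treadmill belt or
wheel rim), a table of marker pairs at known physical separation, and optional
per-frame triangulation residuals.

Conventions used throughout the package: right-handed coordinates with z
vertical (up), units of millimetres, 0-based frame indices, half-open frame
intervals ``[start, end)``, and time in seconds always ``frame / frame_rate``.

The exchange format is a TSV dialect: header ``frame<TAB><label>_x<TAB>
<label>_y<TAB><label>_z ...``, one row per frame, empty cells for missing
samples, UTF-8, LF line endings.  Trial metadata (task, frame rate, known
pairs, surface-marker labels) travels in a YAML/JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Task",
    "FrameInterval",
    "MarkerPairSpec",
    "Trajectory",
    "TrialRecording",
    "TrialParseError",
    "read_trial",
    "write_trial",
    "read_metadata",
    "write_metadata",
]


class Task(str, Enum):
    """Locomotor context of a trial."""

    OF = "OF"   #: open-field arena exploration
    CLB = "CLB"  #: voluntary climbing on a wheel
    TRM = "TRM"  #: running on a motorized treadmill


@dataclass(frozen=True, order=True)
class FrameInterval:
    """Half-open frame interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def duration(self) -> int:
        return self.end - self.start

    def contains(self, frame: int) -> bool:
        return self.start <= frame < self.end

    def to_slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class MarkerPairSpec:
    """Two markers implanted at a known physical separation (mm)."""

    label_a: str
    label_b: str
    known_distance: float

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise ValueError("pair labels must differ")
        if not self.known_distance > 0:
            raise ValueError("known_distance must be positive")


@dataclass
class Trajectory:
    """One marker's positions (n, 3) in mm with a per-frame missing mask.

    Missing frames carry NaN positions; ``filled`` marks frames whose values
    were produced by gap interpolation (they are valid for continuity-needing
    computations but excluded from per-event kinematic measures).
    """

    positions: np.ndarray
    missing: np.ndarray
    filled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (len(self.positions),):
            raise ValueError("missing mask length mismatch")
        # a missing frame never carries a finite position
        self.positions = self.positions.copy()
        self.positions[self.missing] = np.nan
        if self.filled is None:
            self.filled = np.zeros(len(self.positions), dtype=bool)
        else:
            self.filled = np.asarray(self.filled, dtype=bool)
            if self.filled.shape != self.missing.shape:
                raise ValueError("filled mask length mismatch")

    @classmethod
    def from_positions(cls, positions: np.ndarray) -> "Trajectory":
        """Build a trajectory, inferring the missing mask from NaN rows."""
        positions = np.asarray(positions, dtype=float)
        missing = ~np.isfinite(positions).all(axis=1)
        return cls(positions=positions, missing=missing)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]

    def copy(self) -> "Trajectory":
        return Trajectory(
            positions=self.positions.copy(),
            missing=self.missing.copy(),
            filled=self.filled.copy(),
        )


@dataclass
class TrialRecording:
    """All marker trajectories of one trial plus recording metadata."""

    trial_id: str
    task: Task
    markers: dict[str, Trajectory]
    frame_rate: float = 300.0
    surface_markers: dict[str, Trajectory] = field(default_factory=dict)
    known_pairs: list[MarkerPairSpec] = field(default_factory=list)
    residuals: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        self.task = Task(self.task)
        lengths = {len(t) for t in self.markers.values()}
        lengths |= {len(t) for t in self.surface_markers.values()}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent frame counts across trajectories: {lengths}")
        for pair in self.known_pairs:
            for lab in (pair.label_a, pair.label_b):
                if lab not in self.markers:
                    raise ValueError(f"known pair references unknown marker {lab!r}")

    @property
    def n_frames(self) -> int:
        for t in self.markers.values():
            return len(t)
        for t in self.surface_markers.values():
            return len(t)
        return 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Per-frame time stamps in seconds (frame / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def all_trajectories(self) -> dict[str, Trajectory]:
        out = dict(self.markers)
        out.update(self.surface_markers)
        return out

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            trial_id=self.trial_id,
            task=self.task,
            markers={k: t.copy() for k, t in self.markers.items()},
            frame_rate=self.frame_rate,
            surface_markers={k: t.copy() for k, t in self.surface_markers.items()},
            known_pairs=list(self.known_pairs),
            residuals=None
            if self.residuals is None
            else {k: v.copy() for k, v in self.residuals.items()},
        )


class TrialParseError(ValueError):
    """Raised for malformed trajectory files; names the offending line."""


_AXES = ("x", "y", "z")


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write the TSV exchange file for ``trial``.

    Columns are emitted in sorted label order with 6 decimal places so that a
    read/write round trip is bit-stable; missing frames become empty cells.
    """
    path = Path(path)
    trajs = trial.all_trajectories()
    labels = sorted(trajs)
    n = trial.n_frames
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["frame"] + [f"{lab}_{ax}" for lab in labels for ax in _AXES]
        fh.write("\t".join(header) + "\n")
        for i in range(n):
            cells = [str(i)]
            for lab in labels:
                t = trajs[lab]
                if t.missing[i]:
                    cells.extend(["", "", ""])
                else:
                    cells.extend(f"{v:.6f}" for v in t.positions[i])
            fh.write("\t".join(cells) + "\n")


def read_trial(path: str | Path, meta: Mapping | str | Path) -> TrialRecording:
    """Parse a TSV trajectory file plus sidecar metadata into a trial.

    ``meta`` is either a mapping or a path to a YAML/JSON sidecar with keys
    ``trial_id``, ``task``, ``frame_rate``, optional ``known_pairs`` (list of
    ``[label_a, label_b, distance_mm]``), optional ``surface_labels``.
    Empty cells are flagged missing, never silently zero-filled.
    """
    path = Path(path)
    if not isinstance(meta, Mapping):
        meta = read_metadata(meta)

    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    columns = header_line.split("\t")
    if not columns or columns[0] != "frame":
        raise TrialParseError(f"{path}:1: malformed header (expected leading 'frame' column)")
    labels: list[str] = []
    for j, col in enumerate(columns[1:], start=2):
        if len(col) < 3 or col[-2] != "_" or col[-1] not in _AXES:
            raise TrialParseError(f"{path}:1: malformed column name {col!r}")
        lab = col[:-2]
        if lab not in labels:
            labels.append(lab)
    expected = ["frame"] + [f"{lab}_{ax}" for lab in labels for ax in _AXES]
    if columns != expected:
        raise TrialParseError(f"{path}:1: columns must come in x,y,z triplets per label")

    try:
        df = pd.read_csv(path, sep="\t", dtype=float, na_values=[""], keep_default_na=True)
    except ValueError as exc:
        raise TrialParseError(f"{path}: non-numeric cell or ragged row: {exc}") from exc
    if list(df.columns) != expected:
        raise TrialParseError(f"{path}:1: header mismatch after parse")
    # locate ragged rows for a line-numbered error
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1:
                continue
            if line.rstrip("\n").count("\t") != len(columns) - 1:
                raise TrialParseError(f"{path}:{lineno}: expected {len(columns)} cells")

    surface_labels = set(meta.get("surface_labels", []))
    markers: dict[str, Trajectory] = {}
    surface: dict[str, Trajectory] = {}
    for lab in labels:
        pos = df[[f"{lab}_{ax}" for ax in _AXES]].to_numpy(dtype=float)
        incomplete = np.isnan(pos).any(axis=1) & ~np.isnan(pos).all(axis=1)
        if incomplete.any():
            row = int(np.flatnonzero(incomplete)[0])
            raise TrialParseError(
                f"{path}:{row + 2}: marker {lab!r} has a partially empty frame"
            )
        traj = Trajectory.from_positions(pos)
        (surface if lab in surface_labels else markers)[lab] = traj

    known_pairs = [
        MarkerPairSpec(str(a), str(b), float(d)) for a, b, d in meta.get("known_pairs", [])
    ]
    residuals = None
    if meta.get("residuals"):
        residuals = {k: np.asarray(v, dtype=float) for k, v in meta["residuals"].items()}
    return TrialRecording(
        trial_id=str(meta.get("trial_id", path.stem)),
        task=Task(meta.get("task", "OF")),
        markers=markers,
        frame_rate=float(meta.get("frame_rate", 300.0)),
        surface_markers=surface,
        known_pairs=known_pairs,
        residuals=residuals,
    )


def metadata_dict(trial: TrialRecording) -> dict:
    """Sidecar-serializable metadata of a trial."""
    meta: dict = {
        "trial_id": trial.trial_id,
        "task": trial.task.value,
        "frame_rate": trial.frame_rate,
        "known_pairs": [
            [p.label_a, p.label_b, p.known_distance] for p in trial.known_pairs
        ],
        "surface_labels": sorted(trial.surface_markers),
    }
    if trial.residuals is not None:
        meta["residuals"] = {k: [float(v) for v in arr] for k, arr in trial.residuals.items()}
    return meta


def write_metadata(trial: TrialRecording, path: str | Path) -> None:
    path = Path(path)
    meta = metadata_dict(trial)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix == ".json":
            json.dump(meta, fh, indent=1)
        else:
            yaml.safe_dump(meta, fh)


def read_metadata(path: str | Path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
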