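"""Synthetic trial generator with exact ground truth for every pipeline stage.

Emulates the statistical structure the analyses assume for a mouse carrying
paired implanted markers in the three locomotor contexts: intermittent
locomotion (alternating exponential walk/pause segments with smooth speed
ramps), stance/swing ankle cycles with a raised-cosine vertical arc and a
configurable peak-speed phase, additive whole-body tremor with controllable
per-marker phase offsets, a low-amplitude ~8 Hz breathing oscillation on the
shoulder markers, rigid marker pairs at known spacing, white positional
noise, occlusion gaps, and short sub-0.1 mm glitches.

Every stochastic choice flows from one seeded generator, so a fixed seed
yields byte-identical trials.  The returned :class:`GroundTruth` carries the
injected truth each downstream stage is meant to recover: episode intervals,
per-ankle swing intervals with true height/distance/duration, tremor
frequency/amplitude/phases, and the exact lists of injected gaps and
glitches.

Swing-boundary truth is definitional for the acceleration-based detector, so
for OF/CLB trials the stored swing intervals are the boundaries the detector
finds on the clean (noise-free) trajectory, while count, height, distance and
duration are the analytic arc truth; on the treadmill the arcs are
back-to-back and the vertical-minima boundaries coincide with the arc
boundaries exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import FrameInterval, MarkerPairSpec, Task, Trajectory, TrialRecording
from .locomotion import (
    DEFAULT_MAX_DIP_FRAMES,
    DEFAULT_MIN_EPISODE_FRAMES,
    DEFAULT_ONSET_WINDOW_FRAMES,
    DEFAULT_SPEED_THRESHOLD_MM_S,
    detect_locomotion_episodes,
    windowed_speed,
)
from .preprocess import GapRecord, JitterEvent
from .swings import detect_swings_accel

__all__ = [
    "EpisodeModel",
    "GaitModel",
    "TremorModel",
    "BreathingModel",
    "GapModel",
    "GlitchModel",
    "SyntheticConfig",
    "GroundTruth",
    "GenerationError",
    "generate_trial",
    "degrade_trial",
    "BODY_PAIRS",
]

# body-marker template: (pair name, fore-aft offset mm, height mm, default pair spacing mm)
BODY_PAIRS = (
    ("shoulder", 25.0, 35.0, 14.0),
    ("lumbar", 8.0, 32.0, 14.0),
    ("hip", -5.0, 30.0, 14.0),
    ("knee", -12.0, 15.0, 18.0),
)
ANKLE_LATERAL_MM = 9.0
ARENA_PATH_RADIUS_MM = 100.0
WHEEL_RADIUS_MM = 125.0
WHEEL_CENTER_MM = np.array([0.0, 0.0, 250.0])
BELT_MARKER_SPACING_MM = 200.0
BELT_VIEW_HALF_MM = 150.0


class GenerationError(RuntimeError):
    """Requested synthetic events cannot be placed without overlap."""


@dataclass
class EpisodeModel:
    enabled: bool = True
    mean_episode_s: float = 2.0
    mean_pause_s: float = 2.0
    speed_mm_s: float = 150.0
    ramp_s: float = 0.2


@dataclass
class GaitModel:
    enabled: bool = True
    stride_frequency_hz: float = 3.0
    swing_height_mm: float = 10.0
    swing_duration_s: float = 0.18
    peak_speed_offset_s: float = 0.05  # of peak ankle speed after the vertical peak
    speed_profile_sigma: float = 0.12  # width of the swing-speed bump, in swing fractions


@dataclass
class TremorModel:
    enabled: bool = False
    frequency_hz: float = 10.0
    amplitude_mm: float = 0.5
    phase_offsets_rad: dict[str, float] = field(default_factory=dict)  # per marker


@dataclass
class BreathingModel:
    enabled: bool = True
    frequency_hz: float = 8.0
    amplitude_mm: float = 0.2


@dataclass
class GapModel:
    rate_per_marker_minute: float = 0.0
    mean_duration_frames: float = 20.0
    max_duration_frames: int = 120


@dataclass
class GlitchModel:
    rate_per_marker_minute: float = 0.0
    amplitude_mm: float = 0.1
    width_frames: int = 1


@dataclass
class SyntheticConfig:
    seed: int = 0
    duration_s: float = 60.0
    frame_rate: float = 300.0
    task: Task = Task.OF
    n_marker_pairs: int = 4
    pair_distances_mm: tuple[float, ...] | None = None  # overrides template spacings
    episode_model: EpisodeModel = field(default_factory=EpisodeModel)
    gait_model: GaitModel = field(default_factory=GaitModel)
    tremor_model: TremorModel = field(default_factory=TremorModel)
    breathing_model: BreathingModel = field(default_factory=BreathingModel)
    # residual frame-to-frame jitter of marker tracking; well below the
    # 0.05 mm glitch-prominence scale, as in real capture data
    noise_sd_mm: float = 0.01
    gap_model: GapModel = field(default_factory=GapModel)
    glitch_model: GlitchModel = field(default_factory=GlitchModel)

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.frame_rate <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate and duration_s must be positive")
        if not 1 <= self.n_marker_pairs <= len(BODY_PAIRS):
            raise ValueError(f"n_marker_pairs must be in [1, {len(BODY_PAIRS)}]")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key, sub in (
            ("episode_model", EpisodeModel),
            ("gait_model", GaitModel),
            ("tremor_model", TremorModel),
            ("breathing_model", BreathingModel),
            ("gap_model", GapModel),
            ("glitch_model", GlitchModel),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "pair_distances_mm" in d and d["pair_distances_mm"] is not None:
            d["pair_distances_mm"] = tuple(d["pair_distances_mm"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task"] = self.task.value
        return d


@dataclass
class SwingTruth:
    interval: FrameInterval  # boundaries the context's detector should find
    height_mm: float
    distance_mm: float
    duration_s: float
    peak_speed_offset_s: float


@dataclass
class GroundTruth:
    episodes: list[FrameInterval]
    swings: dict[str, list[SwingTruth]]
    tremor: dict | None
    injected_gaps: list[GapRecord]
    injected_glitches: list[JitterEvent]


def _episode_schedule(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame body speed (mm/s) from the alternating walk/pause renewal process."""
    n = int(round(cfg.duration_s * cfg.frame_rate))
    fs = cfg.frame_rate
    em = cfg.episode_model
    speed = np.zeros(n)
    if not em.enabled:
        return speed
    t = 0.0
    segments: list[tuple[float, float]] = []  # (start_s, end_s) of walk
    walking = False
    while t < cfg.duration_s:
        if walking:
            dur = float(np.clip(rng.exponential(em.mean_episode_s), 0.8, 10.0))
            segments.append((t, min(t + dur, cfg.duration_s)))
        else:
            dur = float(np.clip(rng.exponential(em.mean_pause_s), 0.4, 10.0))
        t += dur
        walking = not walking
    times = np.arange(n) / fs
    ramp = em.ramp_s
    for s, e in segments:
        seg = (times >= s) & (times < e)
        u = times[seg]
        env = np.ones(u.shape)
        if ramp > 0:
            rise = (u - s) / ramp
            fall = (e - u) / ramp
            env = np.minimum(1.0, np.minimum(np.clip(rise, 0, None), np.clip(fall, 0, None)))
            env = 0.5 * (1 - np.cos(np.pi * np.clip(env, 0, 1)))
        speed[seg] = em.speed_mm_s * env
    return speed


def _ankle_arc(
    cfg: SyntheticConfig,
    s_body: np.ndarray,
    phase_frac: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Ankle arc-position and height series plus true swing (start, end) frames.

    Strides tile each walking stretch at the stride period; within a stride
    the ankle holds its arc position during stance and advances to the body's
    next stride position during the swing, following a raised-cosine vertical
    arc and a Gaussian-bump horizontal speed profile whose peak sits
    ``peak_speed_offset_s`` after the vertical peak.  ``phase_frac`` offsets
    the stride grid (0.5 for the contralateral ankle).  On the treadmill the
    stance is collapsed so arcs run back-to-back and the vertical minima
    delimit the arcs exactly.
    """
    fs = cfg.frame_rate
    n = len(s_body)
    gm = cfg.gait_model
    arc = s_body.copy()
    z = np.zeros(n)
    swings: list[tuple[int, int]] = []
    if not gm.enabled:
        return arc, z, swings
    T = 1.0 / gm.stride_frequency_hz
    stride_frames = max(int(round(T * fs)), 2)
    if cfg.task is Task.TRM:
        swing_frames = stride_frames  # continuous arcs, instantaneous stance
    else:
        swing_frames = min(max(int(round(gm.swing_duration_s * fs)), 2), stride_frames)
    # walking mask from the true body speed profile
    moving = np.flatnonzero(np.diff(s_body) * fs > 1e-9)
    if moving.size == 0:
        arc[:] = s_body[0]
        return arc, z, swings
    # split into contiguous stretches
    breaks = np.flatnonzero(np.diff(moving) > 1) + 1
    stretches = np.split(moving, breaks)
    u_peak = 0.5 + gm.peak_speed_offset_s / (swing_frames / fs)
    # the ankle advances only during swings; everywhere else it holds its place
    cur = float(s_body[0])
    pos_frame = 0

    def _hold(upto: int) -> None:
        nonlocal pos_frame
        arc[pos_frame:upto] = cur
        pos_frame = upto

    for stretch in stretches:
        f0, f1 = int(stretch[0]), int(stretch[-1]) + 1
        k = f0 + int(round(phase_frac * stride_frames))
        while k + stride_frames <= f1:
            sw_s = k + (stride_frames - swing_frames)
            sw_e = k + stride_frames
            _hold(sw_s)
            a0 = cur
            a1 = float(s_body[min(sw_e, n - 1)])
            m = sw_e - sw_s
            u = np.arange(m + 1) / m  # frame-boundary samples, u[0]=0 .. u[m]=1
            w = np.exp(-0.5 * ((u - u_peak) / gm.speed_profile_sigma) ** 2)
            cum = np.cumsum(w)
            cum = (cum - cum[0]) / (cum[-1] - cum[0])
            arc[sw_s:sw_e] = a0 + (a1 - a0) * cum[:m]
            z[sw_s:sw_e] = 0.5 * gm.swing_height_mm * (1 - np.cos(2 * np.pi * u[:m]))
            if sw_e < n:
                swings.append((sw_s, sw_e))
            cur = a1
            pos_frame = sw_e
            k += stride_frames
    _hold(n)
    return arc, z, swings


def _map_surface_to_lab(
    cfg: SyntheticConfig,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    s_body: np.ndarray,
) -> np.ndarray:
    """Map surface-frame coordinates (arc, lateral, height) into the lab frame."""
    n = len(xs)
    out = np.empty((n, 3))
    if cfg.task is Task.OF:
        R = ARENA_PATH_RADIUS_MM
        alpha = xs / R
        radial = R + ys
        out[:, 0] = radial * np.cos(alpha)
        out[:, 1] = radial * np.sin(alpha)
        out[:, 2] = zs
    elif cfg.task is Task.TRM:
        out[:, 0] = xs - s_body  # belt carries the mouse back: stays near origin
        out[:, 1] = ys
        out[:, 2] = zs
    else:  # CLB: wrap onto the wheel, mouse anchored at phi0 while the wheel rotates
        r = WHEEL_RADIUS_MM
        phi0 = math.pi / 2
        phi = phi0 + (xs - s_body) / r
        radial = r + zs
        out[:, 0] = WHEEL_CENTER_MM[0] + radial * np.sin(phi)
        out[:, 1] = WHEEL_CENTER_MM[1] + ys
        out[:, 2] = WHEEL_CENTER_MM[2] - radial * np.cos(phi)
    return out


def _surface_markers(cfg: SyntheticConfig, s_body: np.ndarray) -> dict[str, Trajectory]:
    n = len(s_body)
    out: dict[str, Trajectory] = {}
    if cfg.task is Task.TRM:
        loop = 3 * BELT_MARKER_SPACING_MM
        for j in range(3):
            x = np.mod(j * BELT_MARKER_SPACING_MM - s_body + BELT_VIEW_HALF_MM, loop) - BELT_VIEW_HALF_MM
            pos = np.column_stack([x, np.full(n, 30.0), np.zeros(n)])
            missing = np.abs(x) > BELT_VIEW_HALF_MM
            pos[missing] = np.nan
            out[f"belt_{j}"] = Trajectory(pos, missing)
    elif cfg.task is Task.CLB:
        r = WHEEL_RADIUS_MM
        theta = -(s_body - s_body[0]) / r  # wheel rotation
        for j in range(8):
            psi = j * math.pi / 4 + theta
            pos = np.column_stack(
                [
                    WHEEL_CENTER_MM[0] + r * np.sin(psi),
                    np.full(n, WHEEL_CENTER_MM[1] - 25.0),
                    WHEEL_CENTER_MM[2] - r * np.cos(psi),
                ]
            )
            out[f"rim_{j}"] = Trajectory(pos, np.zeros(n, dtype=bool))
    return out


def generate_trial(cfg: SyntheticConfig) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    The clean trial is built first (rigid pairs exact, gait arcs, tremor and
    breathing sinusoids), then white positional noise is added, then gaps and
    glitches are injected via :func:`degrade_trial` with the same seed stream.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.frame_rate
    n = int(round(cfg.duration_s * fs))
    times = np.arange(n) / fs

    body_speed = _episode_schedule(cfg, rng)
    s_body = np.concatenate(([0.0], np.cumsum(body_speed[:-1] / fs)))

    markers: dict[str, np.ndarray] = {}
    spacings = {}
    for i, (name, off_x, off_z, default_d) in enumerate(BODY_PAIRS[: cfg.n_marker_pairs]):
        d = (
            cfg.pair_distances_mm[i]
            if cfg.pair_distances_mm is not None and i < len(cfg.pair_distances_mm)
            else default_d
        )
        spacings[name] = d
        for side, sign in (("l", +1.0), ("r", -1.0)):
            xs = s_body + off_x
            ys = np.full(n, sign * d / 2.0)
            zs = np.full(n, off_z)
            markers[f"{name}_{side}"] = _map_surface_to_lab(cfg, xs, ys, zs, s_body)

    # frozen substrate progression: what a perfect surface correction recovers
    # (identity for OF, the surface frame for TRM, the wheel unrolled to its
    # initial orientation for CLB)
    if cfg.task is Task.TRM:
        s_frozen = np.zeros(n)
    else:
        s_frozen = np.full(n, s_body[0])

    swings_truth: dict[str, list[SwingTruth]] = {}
    rel_ankles: dict[str, np.ndarray] = {}
    gm = cfg.gait_model
    for side, sign, phase in (("l", +1.0, 0.0), ("r", -1.0, 0.5)):
        lab = f"ankle_{side}"
        arc, zg, sw = _ankle_arc(cfg, s_body, phase)
        xs = arc - 18.0
        ys = np.full(n, sign * ANKLE_LATERAL_MM)
        zs = zg + 5.0
        pos = _map_surface_to_lab(cfg, xs, ys, zs, s_body)
        markers[lab] = pos
        rel = pos if cfg.task is Task.OF else _map_surface_to_lab(cfg, xs, ys, zs, s_frozen)
        rel_ankles[lab] = rel
        truths = []
        for s, e in sw:
            dist = float(np.linalg.norm(rel[min(e, n - 1)] - rel[s]))
            truths.append(
                SwingTruth(
                    interval=FrameInterval(s, e),
                    height_mm=gm.swing_height_mm,
                    distance_mm=dist,
                    duration_s=(e - s) / fs,
                    peak_speed_offset_s=gm.peak_speed_offset_s,
                )
            )
        swings_truth[lab] = truths

    tremor_truth = None
    if cfg.tremor_model.enabled:
        tm = cfg.tremor_model
        phases = {lab: tm.phase_offsets_rad.get(lab, 0.0) for lab in markers}
        for lab, pos in markers.items():
            osc = tm.amplitude_mm * np.sin(2 * np.pi * tm.frequency_hz * times + phases[lab])
            pos += osc[:, None]
        tremor_truth = {
            "frequency_hz": tm.frequency_hz,
            "amplitude_mm": {lab: tm.amplitude_mm for lab in markers},
            "phase_rad": phases,
        }
    if cfg.breathing_model.enabled:
        bm = cfg.breathing_model
        osc = bm.amplitude_mm * np.sin(2 * np.pi * bm.frequency_hz * times)
        for lab in markers:
            if lab.startswith("shoulder"):
                markers[lab][:, 2] += osc

    # ground-truth episodes from the clean surface-frame reference point
    # (in the lab frame a treadmill mouse barely moves; episode semantics are
    # substrate-relative)
    episodes: list[FrameInterval] = []
    if cfg.episode_model.enabled:
        if cfg.task is Task.OF:
            ref_pos = 0.5 * (markers["hip_l"] + markers["hip_r"])
        elif cfg.task is Task.TRM:
            ref_pos = np.column_stack([s_body, np.zeros(n), np.full(n, 30.0)])
        else:
            # the hip rides ~30 mm above the rim, so its surface-relative
            # speed is scaled by (r + 30) / r
            hip_h = BODY_PAIRS[2][2]
            scale = (WHEEL_RADIUS_MM + hip_h) / WHEEL_RADIUS_MM
            ref_pos = np.column_stack(
                [s_body * scale, np.zeros(n), np.full(n, hip_h)]
            )
        mid = Trajectory.from_positions(ref_pos)
        sp = windowed_speed(mid, DEFAULT_ONSET_WINDOW_FRAMES, fs)
        episodes = [
            ep.interval
            for ep in detect_locomotion_episodes(
                sp,
                DEFAULT_SPEED_THRESHOLD_MM_S,
                DEFAULT_MIN_EPISODE_FRAMES,
                DEFAULT_MAX_DIP_FRAMES,
            )
        ]

    # OF/CLB swing boundaries are definitional: freeze the clean-trajectory
    # detection as the boundary truth (arc truth kept for the other measures)
    if cfg.task in (Task.OF, Task.CLB) and gm.enabled:
        for side in ("l", "r"):
            lab = f"ankle_{side}"
            clean = Trajectory.from_positions(rel_ankles[lab])
            det = detect_swings_accel(clean, fs, context=cfg.task, ankle_label=lab)
            truths = swings_truth[lab]
            if len(det) == len(truths):
                for t, ev in zip(truths, det):
                    t.interval = ev.interval

    if cfg.noise_sd_mm > 0:
        for pos in markers.values():
            pos += rng.normal(0.0, cfg.noise_sd_mm, size=pos.shape)

    known_pairs = [
        MarkerPairSpec(f"{name}_l", f"{name}_r", spacings[name]) for name in spacings
    ]
    trial = TrialRecording(
        trial_id=f"synth-{cfg.task.value.lower()}-{cfg.seed}",
        task=cfg.task,
        markers={lab: Trajectory.from_positions(pos) for lab, pos in sorted(markers.items())},
        frame_rate=fs,
        surface_markers=_surface_markers(cfg, s_body),
        known_pairs=known_pairs,
    )
    degraded, gaps, glitches = _degrade(trial, cfg.gap_model, cfg.glitch_model, rng)
    truth = GroundTruth(
        episodes=episodes,
        swings=swings_truth,
        tremor=tremor_truth,
        injected_gaps=gaps,
        injected_glitches=glitches,
    )
    return degraded, truth


def _degrade(
    trial: TrialRecording,
    gap_model: GapModel,
    glitch_model: GlitchModel,
    rng: np.random.Generator,
) -> tuple[TrialRecording, list[GapRecord], list[JitterEvent]]:
    out = trial.copy()
    n = out.n_frames
    minutes = n / out.frame_rate / 60.0
    gaps: list[GapRecord] = []
    glitches: list[JitterEvent] = []
    for lab in sorted(out.markers):
        traj = out.markers[lab]
        n_gaps = rng.poisson(gap_model.rate_per_marker_minute * minutes)
        occupied: list[tuple[int, int]] = []
        for _ in range(int(n_gaps)):
            dur = int(np.clip(rng.geometric(1.0 / gap_model.mean_duration_frames), 1,
                              gap_model.max_duration_frames))
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(1, max(n - dur - 1, 2)))
                span = (start - 1, start + dur + 1)  # keep gaps separated by >=1 frame
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"cannot place a {dur}-frame gap on {lab} without overlap"
                )
            traj.missing[start:start + dur] = True
            traj.positions[start:start + dur] = np.nan
            gaps.append(GapRecord(lab, FrameInterval(start, start + dur)))
        n_glitches = rng.poisson(glitch_model.rate_per_marker_minute * minutes)
        for _ in range(int(n_glitches)):
            w = int(glitch_model.width_frames)
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(2, max(n - w - 2, 3)))
                span = (start - 3, start + w + 3)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    placed = True
                    break
            if not placed:
                raise GenerationError(f"cannot place a glitch on {lab} without overlap")
            traj.positions[start:start + w, 2] += glitch_model.amplitude_mm
            peak = start + w // 2
            glitches.append(
                JitterEvent(lab, "z", peak, w, glitch_model.amplitude_mm)
            )
    gaps.sort(key=lambda g: (g.marker, g.interval.start))
    glitches.sort(key=lambda g: (g.marker, g.frame))
    return out, gaps, glitches


def degrade_trial(
    trial: TrialRecording,
    gap_model: GapModel | None = None,
    glitch_model: GlitchModel | None = None,
    seed: int = 0,
) -> tuple[TrialRecording, GroundTruth]:
    """Inject occlusion gaps and short glitches into a clean trial.

    Returns the degraded trial and a delta ground truth listing exactly the
    injected events (zero rates are the identity).
    """
    rng = np.random.default_rng(seed)
    out, gaps, glitches = _degrade(
        trial, gap_model or GapModel(), glitch_model or GlitchModel(), rng
    )
    return out, GroundTruth(
        episodes=[], swings={}, tremor=None, injected_gaps=gaps, injected_glitches=glitches
    )
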