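"""Tremor decomposition: band finding, Hilbert amplitude/phase, correlations.

Drug-induced (harmaline-type) tremor appears as an 8-12 Hz oscillation in
every marker trajectory.  Per marker axis, a Welch power spectrum restricted
to 6-18 Hz is smoothed with a generalized-cross-validated smoothing spline
and the individual tremor band is bounded by derivative thresholding (walk
outward from the spectral peak until the absolute derivative drops below 10 %
of its maximum), falling back to the local minima flanking the peak when the
derivative strategy fails.  The trajectory is then zero-phase band-passed to
that band and the Hilbert transform yields instantaneous amplitude (modulus
of the analytic signal) and phase, from which windowed amplitudes and
cross-marker/axis amplitude and phase correlation matrices are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, hilbert, sosfiltfilt, welch

from .io import Task, TrialRecording
from .locomotion import (
    LocomotionEpisode,
    hip_midpoint,
    windowed_speed,
)

__all__ = [
    "TremorProfile",
    "CorrelationMatrices",
    "power_spectrum",
    "smooth_spectrum",
    "find_tremor_band",
    "band_hilbert",
    "windowed_amplitude",
    "tremor_correlations",
    "tremor_profiles",
    "tremor_summary",
    "circular_correlation",
    "DEFAULT_BAND_HZ",
    "DEFAULT_DERIVATIVE_THRESHOLD",
    "DEFAULT_AMPLITUDE_WINDOW_FRAMES",
    "DEFAULT_MOVEMENT_SPLIT_MM_S",
]

DEFAULT_BAND_HZ = (6.0, 18.0)
DEFAULT_DERIVATIVE_THRESHOLD = 0.10
DEFAULT_AMPLITUDE_WINDOW_FRAMES = 150  # ~500 ms at 300 fps
DEFAULT_MOVEMENT_SPLIT_MM_S = 10.0
_AXES = ("x", "y", "z")


@dataclass
class TremorProfile:
    marker: str
    axis: str
    band: tuple[float, float] | None  # Hz; None when no band was found
    peak_frequency: float | None  # Hz
    amplitude_series: np.ndarray | None  # mm per frame
    phase_series: np.ndarray | None  # rad per frame
    edge_valid: np.ndarray | None  # False in the edge-unreliable margins
    mean_amplitude: float | None  # mm, over edge-valid frames

    @property
    def label(self) -> str:
        return f"{self.marker}:{self.axis}"


@dataclass
class CorrelationMatrices:
    labels: list[str]
    amplitude_corr: np.ndarray
    phase_corr: np.ndarray


def power_spectrum(
    signal: np.ndarray,
    frame_rate: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    segment_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD restricted to the tremor search band.

    Hann window, ``segment_s`` segments with 50 % overlap, mean removed.
    The signal must be gap-free and at least two seconds long.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("power_spectrum requires a gap-free (finite) signal")
    nperseg = int(segment_s * frame_rate)
    if len(signal) < nperseg:
        raise ValueError(f"signal shorter than one {segment_s} s segment")
    freqs, pxx = welch(
        signal - signal.mean(),
        fs=frame_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return freqs[sel], pxx[sel]


def smooth_spectrum(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Smoothing-spline fit (GCV-selected smoothing), clipped at zero."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if len(freqs) < 8:
        raise ValueError("need at least 8 frequency bins to smooth")
    spl = make_smoothing_spline(freqs, power)
    return np.clip(spl(freqs), 0.0, None)


def find_tremor_band(
    freqs: np.ndarray,
    smoothed: np.ndarray,
    derivative_threshold: float = DEFAULT_DERIVATIVE_THRESHOLD,
) -> tuple[tuple[float, float], float] | None:
    """Bound the tremor band around the dominant spectral peak.

    Strategy 1 walks outward from the global maximum in each direction,
    stopping at the first bin where |dP/df| falls below
    ``derivative_threshold`` x max|dP/df| after having exceeded it.  If that
    yields an empty, inverted or <2-bin band it is deemed unsuccessful and
    strategy 2 places the boundaries at the local minima flanking the peak
    (band edges when no minimum exists).  A spectrum whose maximum sits on a
    band edge (no interior peak) has no band.
    """
    freqs = np.asarray(freqs, dtype=float)
    p = np.asarray(smoothed, dtype=float)
    n = len(p)
    if n < 3:
        return None
    k = int(np.argmax(p))
    if k == 0 or k == n - 1:
        return None
    if p[k] <= 0 or np.allclose(p, p[0]):
        return None
    peak_freq = float(freqs[k])
    deriv = np.gradient(p, freqs)
    thr = derivative_threshold * float(np.max(np.abs(deriv)))

    def _walk(direction: int) -> int | None:
        seen_above = False
        i = k
        while 0 <= i + direction < n:
            i += direction
            mag = abs(deriv[i])
            if mag >= thr:
                seen_above = True
            elif seen_above:
                return i
        return None

    lo_i = _walk(-1)
    hi_i = _walk(+1)
    if lo_i is not None and hi_i is not None and hi_i - lo_i >= 2:
        return (float(freqs[lo_i]), float(freqs[hi_i])), peak_freq
    # strategy 2: nearest flanking local minima
    lo_i = 0
    for i in range(k - 1, 0, -1):
        if p[i] <= p[i - 1] and p[i] <= p[i + 1]:
            lo_i = i
            break
    hi_i = n - 1
    for i in range(k + 1, n - 1):
        if p[i] <= p[i - 1] and p[i] <= p[i + 1]:
            hi_i = i
            break
    if hi_i - lo_i < 2:
        return None
    return (float(freqs[lo_i]), float(freqs[hi_i])), peak_freq


def band_hilbert(
    signal: np.ndarray,
    band_hz: tuple[float, float],
    frame_rate: float,
    edge_margin_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Instantaneous amplitude and phase of the band-limited signal.

    Zero-phase 4th-order Butterworth band-pass (applied forward-backward)
    followed by the analytic signal; returns (amplitude mm, phase rad,
    edge_valid mask).  The first and last ``edge_margin_s`` are flagged
    unreliable: for the few-hertz-wide bands typical of tremor the filter's
    settling transient spans about a second.
    """
    lo, hi = band_hz
    nyq = frame_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, {nyq}) Hz")
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("band_hilbert requires a gap-free signal")
    sos = butter(4, [lo, hi], btype="bandpass", fs=frame_rate, output="sos")
    filtered = sosfiltfilt(sos, signal - signal.mean())
    analytic = hilbert(filtered)
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    valid = np.ones(len(signal), dtype=bool)
    margin = int(edge_margin_s * frame_rate)
    if margin > 0:
        valid[:margin] = False
        valid[len(signal) - margin:] = False
    return amplitude, phase, valid


def windowed_amplitude(
    amplitude_series: np.ndarray,
    window_frames: int = DEFAULT_AMPLITUDE_WINDOW_FRAMES,
) -> np.ndarray:
    """Centered moving average of instantaneous amplitude.

    Edges average over the available part of the window (no padding values
    are invented).
    """
    a = np.asarray(amplitude_series, dtype=float)
    n = len(a)
    finite = np.isfinite(a)
    csum = np.concatenate(([0.0], np.cumsum(np.where(finite, a, 0.0))))
    ccnt = np.concatenate(([0.0], np.cumsum(finite.astype(float))))
    t = np.arange(n)
    lo = np.clip(t - window_frames // 2, 0, n)
    hi = np.clip(t + (window_frames - 1) // 2 + 1, 0, n)
    num = csum[hi] - csum[lo]
    den = ccnt[hi] - ccnt[lo]
    out = np.full(n, np.nan)
    np.divide(num, den, out=out, where=den > 0)
    return out


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation of two phase series.

    Computed with the O(n) double-angle identity equivalent to the pairwise
    definition; +1 for phase-locked series at any fixed offset, -1 for
    reflected phases.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    A = float(np.cos(a) @ np.cos(b))
    B = float(np.sin(a) @ np.sin(b))
    C = float(np.cos(a) @ np.sin(b))
    D = float(np.sin(a) @ np.cos(b))
    E = float(np.sum(np.cos(2 * a)))
    F = float(np.sum(np.sin(2 * a)))
    G = float(np.sum(np.cos(2 * b)))
    H = float(np.sum(np.sin(2 * b)))
    denom_sq = (n**2 - E**2 - F**2) * (n**2 - G**2 - H**2)
    if denom_sq <= 0:
        return float("nan")
    return 4.0 * (A * B - C * D) / float(np.sqrt(denom_sq))


def tremor_correlations(profiles: list[TremorProfile]) -> CorrelationMatrices:
    """Amplitude (Pearson) and phase (circular) correlation matrices.

    Profiles without a detected band are skipped; frames flagged
    edge-unreliable in any retained profile are excluded everywhere so all
    entries share one frame set.  Entries involving a constant series are
    NaN (undefined), the diagonal is 1 and both matrices are symmetric.
    """
    kept = [p for p in profiles if p.band is not None]
    if len(kept) < 2:
        raise ValueError("need at least two profiles with detected bands")
    valid = np.logical_and.reduce([p.edge_valid for p in kept])
    if valid.sum() < 3:
        raise ValueError("no common edge-valid frames")
    labels = [p.label for p in kept]
    amps = np.array([p.amplitude_series[valid] for p in kept])
    phases = np.array([p.phase_series[valid] for p in kept])
    m = len(kept)
    amp_corr = np.eye(m)
    ph_corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if np.ptp(amps[i]) == 0 or np.ptp(amps[j]) == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(amps[i], amps[j])[0, 1])
            amp_corr[i, j] = amp_corr[j, i] = r
            ph_corr[i, j] = ph_corr[j, i] = circular_correlation(phases[i], phases[j])
    return CorrelationMatrices(labels=labels, amplitude_corr=amp_corr, phase_corr=ph_corr)


def tremor_profiles(
    trial: TrialRecording,
    markers: list[str] | None = None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> list[TremorProfile]:
    """Per marker-axis tremor decomposition for a (preprocessed) trial."""
    labels = markers if markers is not None else sorted(trial.markers)
    out: list[TremorProfile] = []
    for lab in labels:
        traj = trial.markers[lab]
        for ax_i, ax in enumerate(_AXES):
            sig = traj.positions[:, ax_i]
            profile = TremorProfile(lab, ax, None, None, None, None, None, None)
            if np.isfinite(sig).all():
                freqs, pxx = power_spectrum(sig, trial.frame_rate, band_hz)
                smoothed = smooth_spectrum(freqs, pxx)
                found = find_tremor_band(freqs, smoothed)
                if found is not None:
                    band, peak = found
                    amp, phase, valid = band_hilbert(sig, band, trial.frame_rate)
                    profile = TremorProfile(
                        lab,
                        ax,
                        band,
                        peak,
                        amp,
                        phase,
                        valid,
                        float(amp[valid].mean()),
                    )
            out.append(profile)
    return out


def tremor_summary(
    trial: TrialRecording,
    episodes: list[LocomotionEpisode] | None = None,
    markers: list[str] | None = None,
    movement_split_mm_s: float = DEFAULT_MOVEMENT_SPLIT_MM_S,
    amplitude_window_frames: int = DEFAULT_AMPLITUDE_WINDOW_FRAMES,
) -> dict:
    """Marker- and axis-level tremor summaries with a movement split.

    Per-marker peak frequency and mean amplitude average the marker's axes
    (axes without a band are skipped); per-axis amplitude averages markers.
    Windowed amplitudes are split at a reference-point (hip-midpoint) speed
    of ``movement_split_mm_s`` into moving and still frames.
    """
    profiles = tremor_profiles(trial, markers)
    per_marker: dict[str, dict] = {}
    for p in profiles:
        per_marker.setdefault(p.marker, {"peaks": [], "amps": []})
        if p.band is not None:
            per_marker[p.marker]["peaks"].append(p.peak_frequency)
            per_marker[p.marker]["amps"].append(p.mean_amplitude)
    marker_summary = {
        lab: {
            "peak_frequency_hz": float(np.mean(d["peaks"])) if d["peaks"] else None,
            "mean_amplitude_mm": float(np.mean(d["amps"])) if d["amps"] else None,
        }
        for lab, d in per_marker.items()
    }
    axis_summary = {}
    for ax in _AXES:
        amps = [p.mean_amplitude for p in profiles if p.axis == ax and p.band is not None]
        axis_summary[ax] = float(np.mean(amps)) if amps else None

    moving_amp = still_amp = None
    with_band = [p for p in profiles if p.band is not None]
    if with_band:
        try:
            ref = hip_midpoint(trial)
            speed = windowed_speed(ref, 10, trial.frame_rate).values
        except KeyError:
            speed = None
        if speed is not None:
            moving = np.zeros(len(speed), dtype=bool)
            defined = np.isfinite(speed)
            moving[defined] = speed[defined] > movement_split_mm_s
            pooled_moving, pooled_still = [], []
            for p in with_band:
                wa = windowed_amplitude(p.amplitude_series, amplitude_window_frames)
                ok = p.edge_valid & np.isfinite(wa) & defined
                pooled_moving.append(wa[ok & moving])
                pooled_still.append(wa[ok & ~moving])
            pm = np.concatenate(pooled_moving)
            ps = np.concatenate(pooled_still)
            moving_amp = float(pm.mean()) if pm.size else None
            still_amp = float(ps.mean()) if ps.size else None
    return {
        "per_marker": marker_summary,
        "per_axis_mean_amplitude_mm": axis_summary,
        "amplitude_moving_mm": moving_amp,
        "amplitude_still_mm": still_amp,
        "profiles": profiles,
    }
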