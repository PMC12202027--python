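"""Independent brute-force reference implementations used by the tests.

Each oracle is written as a direct, unoptimized transcription of the
operation's definition — per-frame Python loops, no shared code with the
package — so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def gaps_bruteforce(missing: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of missing frames by linear scan."""
    out = []
    i = 0
    n = len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def fill_bruteforce(positions: np.ndarray, missing: np.ndarray, max_gap: int) -> np.ndarray:
    """Per-axis linear interpolation of interior gaps shorter than max_gap."""
    out = positions.copy()
    n = len(out)
    for s, e in gaps_bruteforce(missing):
        if s == 0 or e == n or (e - s) >= max_gap:
            continue
        for ax in range(3):
            a, b = out[s - 1, ax], out[e, ax]
            for k in range(s, e):
                frac = (k - (s - 1)) / (e - (s - 1))
                out[k, ax] = a + frac * (b - a)
    return out


def windowed_speed_bruteforce(
    positions: np.ndarray, window: int, fs: float
) -> np.ndarray:
    """Centered endpoint-displacement speed, frame by frame."""
    n = len(positions)
    h = max(window // 2, 1)
    out = np.full(n, np.nan)
    for t in range(n):
        a, b = t - h, t + h
        if a < 0 or b >= n:
            continue
        pa, pb = positions[a], positions[b]
        if np.isfinite(pa).all() and np.isfinite(pb).all():
            out[t] = float(np.linalg.norm(pb - pa)) / (2 * h / fs)
    return out


def episodes_bruteforce(
    speed: np.ndarray, threshold: float, min_frames: int, max_dip: int
) -> list[tuple[int, int]]:
    """Run-length scan with iterative dip merging until fixpoint."""
    above = [bool(np.isfinite(v) and v > threshold) for v in speed]
    segs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            segs.append([i, j])
            i = j
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(segs) - 1):
            if segs[k + 1][0] - segs[k][1] <= max_dip:
                segs[k] = [segs[k][0], segs[k + 1][1]]
                del segs[k + 1]
                changed = True
                break
    return [tuple(s) for s in segs if s[1] - s[0] >= min_frames]


def moving_average_bruteforce(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at edges, NaN-aware."""
    n = len(values)
    out = np.full(n, np.nan)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    for t in range(n):
        a = max(t - half_hi, 0)
        b = min(t + half_lo + 1, n)
        # np.convolve 'same' centers the kernel with the extra tap on the left
        window_vals = [v for v in values[a:b] if np.isfinite(v)]
        if window_vals:
            out[t] = float(np.mean(window_vals))
    return out


def ecdf_bruteforce(values: list[float], x: float) -> float:
    if not values:
        return float("nan")
    return sum(1 for v in values if v <= x) / len(values)


def circular_corr_pairwise(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee coefficient by the O(n^2) pairwise-difference definition."""
    num = 0.0
    da = 0.0
    db = 0.0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            sa = np.sin(a[i] - a[j])
            sb = np.sin(b[i] - b[j])
            num += sa * sb
            da += sa * sa
            db += sb * sb
    return num / np.sqrt(da * db)
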