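"""Decompose whole-body tremor and correlate it across the body.

An immobile mouse carries a 10 Hz, 0.4 mm tremor with known per-marker phase
offsets.  Per marker axis: Welch spectrum in 6-18 Hz, spline smoothing,
derivative-threshold band boundaries, zero-phase band-pass and Hilbert
transform.  Amplitude correlations are Pearson; phase correlations use the
Fisher-Lee circular coefficient (phase-locked series at any fixed offset
score +1).
"""

import numpy as np

from mocapkit.fixtures import tremor_trial_config
from mocapkit.synthetic import generate_trial
from mocapkit.tremor import tremor_correlations, tremor_profiles

cfg = tremor_trial_config(
    seed=5, duration_s=40.0, frequency_hz=10.0, amplitude_mm=0.4,
    phase_offsets={"hip_l": 0.0, "knee_l": 0.45, "shoulder_l": 1.1},
)
trial, truth = generate_trial(cfg)
markers = ["hip_l", "knee_l", "shoulder_l"]
profiles = tremor_profiles(trial, markers=markers)

for p in profiles:
    if p.axis == "z" and p.band is not None:
        lo, hi = p.band
        print(f"{p.marker}:z  band {lo:5.2f}-{hi:5.2f} Hz, "
              f"peak {p.peak_frequency:5.2f} Hz, amplitude {p.mean_amplitude:.3f} mm")

cm = tremor_correlations([p for p in profiles if p.axis == "z"])
print("phase correlation matrix (z axes):")
with np.printoptions(precision=3, suppress=True):
    print(cm.phase_corr)
print("All entries near 1: the tremor is phase-locked across the whole body,")
print("the signature of a centrally generated oscillation.")
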