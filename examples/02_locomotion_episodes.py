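"""Segment locomotory episodes and summarize whole-trial locomotion.

The hip-midpoint speed (displacement over a 100-frame window) defines
locomotory episodes: speed above 40 mm/s for at least 100 frames, tolerating
interior dips of up to 50 frames.  Totals use the 1 s speed window.
"""

from mocapkit.fixtures import gait_trial_config
from mocapkit.io import Task
from mocapkit.locomotion import (
    detect_locomotion_episodes,
    hip_midpoint,
    trial_locomotion_summary,
    windowed_speed,
)
from mocapkit.synthetic import generate_trial

trial, truth = generate_trial(gait_trial_config(seed=2, task=Task.OF, duration_s=30.0))
ref = hip_midpoint(trial)
fs = trial.frame_rate
episodes = detect_locomotion_episodes(windowed_speed(ref, 100, fs), reference=ref)
summary = trial_locomotion_summary(ref, episodes, windowed_speed(ref, int(fs), fs))

for ep in episodes:
    print(
        f"episode {ep.interval.start / fs:6.2f}-{ep.interval.end / fs:6.2f} s, "
        f"mean speed {ep.mean_speed:6.1f} mm/s"
    )
print(f"distance traveled: {summary['distance_traveled_mm']:.0f} mm")
print(f"time locomoting:   {summary['time_locomoting_s']:.2f} s")
print(f"mean locomotory speed: {summary['mean_locomotory_speed_mm_s']:.1f} mm/s")
print(f"(generator ground truth: {len(truth.episodes)} episodes)")
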