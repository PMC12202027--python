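"""Motion index and the minimal-detectable-movement sweep.

The motion index (MI) averages every marker's 10-frame windowed speed and so
captures micro-movements that reference-point speed misses.  The sweep then
asks: if the capture system could not resolve displacements below some floor,
at what floor would two groups differing only in stationary micro-movement
(0.60 vs 0.29 mm per 10 frames, the scale of a sedative-like drug effect)
become statistically indistinguishable?
"""

import numpy as np

from mocapkit.fixtures import gait_trial_config
from mocapkit.io import Task
from mocapkit.locomotion import detect_locomotion_episodes, hip_midpoint, windowed_speed
from mocapkit.motion_index import motion_index, noise_floor_sweep, project_residual_to_2d
from mocapkit.synthetic import generate_trial

trial, _ = generate_trial(gait_trial_config(seed=3, task=Task.OF, duration_s=20.0))
episodes = detect_locomotion_episodes(
    windowed_speed(hip_midpoint(trial), 100, trial.frame_rate)
)
res = motion_index(trial, episodes)
print(f"mean MI while locomoting: {res.mean_mi_locomotory:7.1f} mm/s")
print(f"mean MI while stationary: {res.mean_mi_stationary:7.1f} mm/s")

rng = np.random.default_rng(3)
veh = np.clip(rng.normal(0.60, 0.30, 2000), 0, None)
drug = np.clip(rng.normal(0.29, 0.27, 2000), 0, None)
floors = np.linspace(0, 1.5, 31)
p = noise_floor_sweep(veh, drug, floors)
crossover = floors[np.argmax(p > 0.05)]
print(f"rank-sum p at zero floor: {p[0]:.2e} (groups clearly distinct)")
print(f"significance lost above a {crossover:.2f} mm floor")
print(
    "estimated capture noise floor:"
    f" {project_residual_to_2d(0.35):.2f} mm (2D projection of a 0.35 mm 3D residual)"
    " - well below the separation scale"
)
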