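import numpy as np
import pytest

from mocapkit import fixtures as fx
from mocapkit.io import Task
from mocapkit.synthetic import generate_trial


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def trm_gait():
    """Treadmill running trial with ground truth (10 s, ~20 strides/ankle)."""
    cfg = fx.gait_trial_config(seed=11, task=Task.TRM, duration_s=10.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def of_gait():
    """Open-field intermittent locomotion trial with ground truth."""
    cfg = fx.gait_trial_config(seed=11, task=Task.OF, duration_s=10.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def clb_gait():
    """Climbing-wheel trial with ground truth."""
    cfg = fx.gait_trial_config(seed=11, task=Task.CLB, duration_s=10.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def tremor_trial():
    """Immobile tremoring mouse: 10 Hz, 0.5 mm, known per-marker phases."""
    cfg = fx.tremor_trial_config(
        seed=5,
        duration_s=30.0,
        phase_offsets={"hip_l": 0.0, "knee_l": 0.4, "shoulder_l": 1.2},
    )
    return generate_trial(cfg)
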