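import numpy as np
import pytest

from squatkin import (
    TrialParams,
    generate_trial,
    detect_repetitions,
    compute_kinematics,
)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free 5-rep trial at the study tempo (45 bpm, 100 Hz)."""
    params = TrialParams(tempo_bpm=45.0, n_reps=5, noise_sd_m=0.0, seed=7)
    return params, generate_trial(params)


@pytest.fixture(scope="session")
def clean_kin(clean_trial):
    _, traj = clean_trial
    return compute_kinematics(traj, cutoff_hz=None)


@pytest.fixture(scope="session")
def clean_cycles(clean_kin):
    return detect_repetitions(clean_kin)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
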