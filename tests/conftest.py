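import warnings

import numpy as np
import pandas as pd
import pytest

import yokedbml.cohort as co
import yokedbml.glm as fl
import yokedbml.paradigm as par

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_session():
    return par.generate_trajectory(par.MotionConfig(seed=0))


@pytest.fixture(scope="session")
def default_behavior(default_session):
    return par.simulate_wheel_trials(default_session, par.WheelConfig(), seed=0)


@pytest.fixture(scope="session")
def default_events(default_behavior) -> pd.DataFrame:
    beh = default_behavior
    return pd.DataFrame({
        "onset": beh.onsets(), "duration": beh.durations(),
        "trial_type": "stressor",
        "n_presses": beh.press_counts("CTL").astype(float),
    })


@pytest.fixture(scope="session")
def default_design(default_events, default_session):
    n_tr = int(default_session.config.n_runs * default_session.config.run_duration / 1.25)
    run_ix = np.repeat(np.arange(default_session.config.n_runs), n_tr // 6)
    motion = co.simulate_motion_params(n_tr, run_ix, seed=0)
    return fl.build_design(default_events, default_session, motion=motion)
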