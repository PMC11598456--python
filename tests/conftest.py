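import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gaitstab.gait_geometry import (
    compute_com,
    filter_trial,
    gait_frame,
    pelvis_pose,
    toe_centre,
)
from gaitstab.pelvis_features import six_axis_velocity, steps_from_events
from gaitstab.stability import mos_series
from gaitstab.synthetic_data import WalkerSpec, make_walker


@pytest.fixture(scope="session")
def walker():
    """Default walker fixture; cadence 120 puts every event on the frame grid."""
    spec = WalkerSpec(cadence=120.0, n_steps=8, seed=0)
    return make_walker(spec)


@pytest.fixture(scope="session")
def walker_processed(walker):
    """Walker run through the geometry stages with ground-truth events."""
    trial, truth = walker
    filtered = filter_trial(trial)
    com_f = compute_com(filtered)
    frame = gait_frame(trial.times, com_f, truth.events)
    pose = pelvis_pose(filtered)
    vel6 = six_axis_velocity(pose, frame, trial.rate)
    toes = {s: toe_centre(filtered, s) for s in ("L", "R")}
    series = mos_series(trial.times, com_f, toes, truth.events, frame)
    steps = [st for st in steps_from_events(truth.events)
             if any(abs(st.t_start - t0) < 1e-9 for t0 in truth.critical["t_start"])]
    return {
        "trial": trial, "truth": truth, "filtered": filtered, "com_f": com_f,
        "frame": frame, "pose": pose, "vel6": vel6, "series": series, "steps": steps,
    }


@pytest.fixture(scope="session")
def latent_default():
    from gaitstab.synthetic_data import LatentSpec, make_latent_dataset

    return make_latent_dataset(LatentSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
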