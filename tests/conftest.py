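import numpy as np
import pytest

import hoofline as hl
from hoofline.session import AnalysisOptions


SIDE_CAM = hl.default_cameras()[2]      # static 90 deg right side, 100 cm


@pytest.fixture(scope="session")
def side_cam():
    return SIDE_CAM


@pytest.fixture(scope="session")
def opts():
    return AnalysisOptions()


@pytest.fixture(scope="session")
def clean_world():
    """Noiseless symmetric horse, 20 s."""
    params = hl.GaitParams(duration=20.0, noise_sigma=0.0)
    return params, hl.simulate_gait(params)


@pytest.fixture(scope="session")
def clean_traj(clean_world):
    params, world = clean_world
    return hl.project(world, SIDE_CAM)


@pytest.fixture(scope="session")
def noisy_traj(clean_world):
    params, world = clean_world
    return hl.corrupt(hl.project(world, SIDE_CAM), 1.0, 0.0, seed=1)


def stance_mask_from_events(events, leg, n_frames):
    mask = np.zeros(n_frames, dtype=bool)
    for ev in events:
        if ev.leg == leg:
            mask[ev.start:ev.end + 1] = True
    return mask
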