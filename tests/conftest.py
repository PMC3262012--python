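import numpy as np
import pytest

import pcmotion as pm


@pytest.fixture(scope="session")
def stage11():
    return pm.get_preset("pc_stage11")


@pytest.fixture(scope="session")
def quiet_preset(stage11):
    """Stage-11 preset with drift events and nucleus drift switched off."""
    return stage11.replace(event_rate_per_s=0.0, nucleus_drift_speed_um_s=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_track(xy, dt=0.25, object_id=0, nucleus_id=0, intensity=None):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(xy.shape[0]) * dt
    return pm.Track(object_id=object_id, nucleus_id=nucleus_id, t_s=t,
                    xy_um=xy, intensity=intensity)
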