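import numpy as np
import pytest

from wmcircuit.datatypes import Recording
from wmcircuit.simulate import SimConfig, synthesize_session


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_trials_per_load=4,
        n_channels={"HIP": 2, "AMY": 2},
        rate_hz=200.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return synthesize_session(small_cfg)


@pytest.fixture(scope="session")
def zscored_power(small_session):
    from wmcircuit.experiments import _zscored_power

    rec, tt, _ = small_session
    return _zscored_power(rec, tt, n_boot=200, seed=11)


@pytest.fixture()
def two_channel_recording():
    rng = np.random.default_rng(0)
    return Recording(
        samples=rng.standard_normal((2, 1000)),
        rate_hz=1000.0,
        channel_names=["HIP1", "AMY1"],
        channel_region={"HIP1": "HIP", "AMY1": "AMY"},
    )
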