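from __future__ import annotations

import numpy as np
import pytest

from microsacc.core import DetectorParams, GazeTrace
from microsacc.synthetic_gaze import SimConfig, simulate_trial


def make_trace(x, y=None, rate=500.0, valid=None, eye="averaged", unit="deg"):
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    if valid is None:
        valid = np.ones_like(x, dtype=bool)
    return GazeTrace(eye=eye, x=x, y=np.asarray(y, float),
                     valid=np.asarray(valid, bool), rate_hz=rate, unit=unit)


@pytest.fixture(scope="session")
def sim_config():
    """Short binocular trials keep the suite fast."""
    return SimConfig(trial_s=6.0)


@pytest.fixture(scope="session")
def sim_trial(sim_config):
    return simulate_trial(sim_config, seed=7)


@pytest.fixture
def default_params():
    return DetectorParams()
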