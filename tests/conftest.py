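import numpy as np
import pytest

from lvpet import kinetics as kin
from lvpet import phantom as ph
from lvpet.imaging import expand_schedule


@pytest.fixture(scope="session")
def frame_times():
    """Start/end times of the default 22-frame dynamic schedule."""
    durations = expand_schedule("1x10,8x5,4x10,2x15,3x20,2x30,2x60")
    ends = np.cumsum(durations)
    starts = np.concatenate([[0.0], ends[:-1]])
    return starts, ends


@pytest.fixture(scope="session")
def blood_inputs(frame_times):
    """Densely sampled gamma-variate arterial/venous input functions."""
    t = np.arange(0.5, 360.5, 0.5)
    ca, cv = ph.blood_curves(ph.PhantomConfig(), t)
    return kin.InputFunctions(times=t, ca=ca, cv=cv)


@pytest.fixture(scope="session")
def small_cfg():
    """A coarse phantom configuration cheap enough for per-test use."""
    return ph.PhantomConfig(shape=(48, 48, 48), spacing_mm=4.0, seed=3)


@pytest.fixture(scope="session")
def small_gated(small_cfg):
    return ph.make_gated_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_dynamic(small_cfg):
    return ph.make_dynamic_phantom(small_cfg)


@pytest.fixture(scope="session")
def neck_phantom():
    """Noiseless LV + atrium phantom (no RV, no myocardium) at full resolution."""
    cfg = ph.PhantomConfig(noise=False, include_rv=False, include_myocardium=False)
    return ph.make_gated_phantom(cfg)
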