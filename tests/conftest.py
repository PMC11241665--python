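import numpy as np
import pytest

from ipsckit import synthgen
from ipsckit.traces import SweepTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sham_params():
    return synthgen.preset("sham")


@pytest.fixture
def bbbd_params():
    return synthgen.preset("bbbd")


@pytest.fixture
def flat_trace():
    """1 s of flat -50 pA current, no stimuli."""
    return SweepTrace(samples=np.full(10_000, -50.0), dt=0.1,
                      protocol="minis")


def make_trace(samples, dt=0.1, **kw):
    return SweepTrace(samples=np.asarray(samples, float), dt=dt, **kw)
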