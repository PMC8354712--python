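import numpy as np
import pytest

from reachcost.design import TargetSpec
from reachcost.kinematics import HandTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(positions, t0=0):
    """Build a HandTrace from a list of (x, y) samples at 10-ms spacing."""
    xy = np.asarray(positions, float)
    t = t0 + 10 * np.arange(len(xy))
    return HandTrace(t=t, x=xy[:, 0], y=xy[:, 1])


@pytest.fixture
def straight_reach():
    """A stationary hold then a straight 10-sample reach to the 60-degree target."""
    target = TargetSpec(60, True)
    hold = [(0.0, 0.0)] * 20
    steps = np.linspace(0, 1, 12)[1:]
    move = [tuple(s * target.center) for s in steps]
    settle = [tuple(target.center)] * 5
    return make_trace(hold + move + settle), target
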