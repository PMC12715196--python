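import numpy as np
import pytest

from gatedflim import GateTimeline, IRFParams


@pytest.fixture
def timeline():
    """Default acquisition clock: 25 gates, 2 ns step, 5 ns width, 50 ns period."""
    return GateTimeline(n_gates=25, gate_width_ns=5.0, gate_step_ns=2.0,
                        first_delay_ns=0.0, laser_period_ns=50.0)


@pytest.fixture
def irf():
    """Default parametrized IRF used by the simulator."""
    return IRFParams(sigma=0.25, gate_width=5.0, t0=5.0, amplitude=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
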