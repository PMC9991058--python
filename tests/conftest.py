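import numpy as np
import pytest

from cracdi import (
    BufferSpec,
    MicrodomainModel,
    VoltageProtocol,
    VoltageSegment,
    sensitized,
    wt_like,
)


@pytest.fixture
def egta10():
    return MicrodomainModel(buffer=BufferSpec.egta(10))


@pytest.fixture
def bapta8():
    return MicrodomainModel(buffer=BufferSpec.bapta(8))


@pytest.fixture
def step_minus100():
    """Single 300 ms hyperpolarizing step to -100 mV from +30 mV holding."""
    return VoltageProtocol.single_sweep(
        [VoltageSegment.step(0.300, -0.100)], sweep_interval=0.35
    )


@pytest.fixture
def wt_model():
    return wt_like()


@pytest.fixture
def sensitized_model():
    return sensitized()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
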