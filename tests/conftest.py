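import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecapdeconv import SampledWaveform, TimeGrid

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def default_grid() -> TimeGrid:
    """Recording window 0-2.2 ms at dt = 0.005 ms."""
    return TimeGrid(0.0, 2.2, 0.005)


@pytest.fixture()
def flat_tail_wave() -> SampledWaveform:
    """A synthetic biphasic wave on 0-2.2 ms whose tail (>= 1.5 ms) is flat."""
    g = TimeGrid(0.0, 2.2, 0.01)
    t = g.times
    vals = -0.4 * np.exp(-((t - 0.3) ** 2) / (2 * 0.05**2)) + 0.1 * np.exp(
        -((t - 0.6) ** 2) / (2 * 0.1**2)
    )
    return SampledWaveform(g.start, g.dt, vals, "biphasic")
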