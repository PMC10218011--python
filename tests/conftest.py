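import numpy as np
import pytest

from blockbold import (
    DEFAULT_SCHEDULE, MotionTrace, NoiseSpec, default_hrf, default_scene,
)


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def hrf():
    return default_hrf()


@pytest.fixture()
def quiet_trace():
    """Factory for low-motion traces of a given length."""

    def make(n=88, seed=0, sd=0.02):
        rng = np.random.default_rng(seed)
        kernel = np.ones(5) / 5.0
        cols = [np.convolve(rng.normal(0, sd, n + 4), kernel, "same")[:n]
                for _ in range(6)]
        return MotionTrace(np.column_stack(cols), 3.0)

    return make


@pytest.fixture()
def noiseless():
    return NoiseSpec(white_sd_pct=0.0, ar1=0.0, drift_pct=0.0, seed=0)
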