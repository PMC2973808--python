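import numpy as np
import pytest

from sisa import SISaParams, make_benchmark_panel


@pytest.fixture(scope="session")
def obesity_params() -> SISaParams:
    """Rates measured for obesity at the latest exam interval (per year)."""
    return SISaParams(a=0.02, g=0.04, beta=0.005)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced synthetic panel (fast) with known ground truth."""
    return make_benchmark_panel(n=1200, waves=5, wave_spacing=4.0, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
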