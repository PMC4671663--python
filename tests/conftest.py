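import numpy as np
import pytest

from soundhue.colour import build_hybrid_grid
from soundhue.simulate import GeneratorConfig, generate_stimuli


@pytest.fixture(scope="session")
def coarse_grid():
    """Step-10 hybrid grid: small enough for exhaustive-scan oracles."""
    return build_hybrid_grid(10.0)


@pytest.fixture(scope="session")
def fine_grid():
    """The full step-2 production grid (built once per session)."""
    return build_hybrid_grid(2.0)


@pytest.fixture(scope="session")
def stimulus_pool():
    cfg = GeneratorConfig(n_stimuli=60, seed=7)
    return generate_stimuli(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
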