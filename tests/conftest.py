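import numpy as np
import pytest

import vesiflux as vf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """Fast default-convention config for simulator unit tests."""
    return vf.SimConfig(n_vesicles=10, density=None, stop_events=60,
                        max_time=200.0, seed=42)
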