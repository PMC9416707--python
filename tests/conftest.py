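import numpy as np
import pytest

import driftwalk as dw


@pytest.fixture(scope="session")
def rho085_structure():
    """1024x1024 random disk field at matrix fraction 0.85 (fixed seed)."""
    return dw.generate_artificial(0.85, 1024, 1024, seed=11)


@pytest.fixture(scope="session")
def small_obstacle_structure():
    """Small random field for fast collision / invariant checks."""
    return dw.generate_artificial(0.7, 64, 64, size_dist=("lognormal", 2.0, 0.4), seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
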