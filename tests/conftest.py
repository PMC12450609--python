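import logging

import numpy as np
import pytest
from hypothesis import settings

from antcomp.simulate import simulate_community

logging.getLogger("antcomp").setLevel(logging.ERROR)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic campaign reused across integration tests."""
    return simulate_community(T=4, S=6, B=6, P=6, n_assays=120, rho=-0.9, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
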