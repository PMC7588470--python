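import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import strainrisk as sr

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def membrane_grid():
    """Noiseless membrane-scaling grid factory: eps = eps0 / (tau * eta)."""
    fr = np.array(sr.FRACTIONS)

    def make(eps0: float) -> sr.StrainGrid:
        return sr.StrainGrid(eps0 / np.outer(fr, fr))

    return make


@pytest.fixture
def random_grid(rng):
    """Random strictly positive 4x4 strain grid factory."""

    def make() -> sr.StrainGrid:
        return sr.StrainGrid(rng.uniform(0.02, 1.8, (4, 4)))

    return make
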