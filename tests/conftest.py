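import numpy as np
import pytest
from hypothesis import settings

import agestage as ag

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy2():
    """Two-stage worked example (juvenile/adult with fertility 2)."""
    return ag.fixtures.toy_two_stage()


@pytest.fixture
def leslie5():
    """Five-age Leslie schedule with growing population (lambda > 1)."""
    return ag.fixtures.leslie_fixture(
        p=np.array([0.8, 0.7, 0.6, 0.5]),
        f=np.array([0.0, 0.3, 0.8, 1.2, 1.5]),
    )


@pytest.fixture
def lefko5():
    """A deterministic 5-stage random life cycle."""
    return ag.fixtures.random_lefkovitch(5, seed=11)


def random_fixture_pool(n, seed=0, s_range=(2, 8), omega_range=(3, 40)):
    """Deterministic pool of (stage set, omega) pairs for sweeping checks."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        s = int(rng.integers(s_range[0], s_range[1] + 1))
        omega = int(rng.integers(omega_range[0], omega_range[1] + 1))
        out.append((ag.fixtures.random_lefkovitch(s, seed=10_000 + 97 * k), omega))
    return out
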