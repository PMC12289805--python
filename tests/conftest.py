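import numpy as np
import pytest

from pclattice.equilibria import ModelParams, equilibrium_branches
from pclattice.nonlinearity import SigmoidParams


@pytest.fixture(scope="session")
def sg16():
    return SigmoidParams(mu=16.0, theta=0.5)


@pytest.fixture(scope="session")
def params_center():
    """Reference parameter point used throughout the paper's figures."""
    return ModelParams(theta=0.5, mu=16.0, p=0.1, q=0.5)


@pytest.fixture(scope="session")
def branches_center():
    return equilibrium_branches(0.5, 16.0)


@pytest.fixture(scope="session")
def branches_035():
    return equilibrium_branches(0.35, 16.0)


#: reduced scale for wave-speed estimates in unit tests (signs and symmetry
#: are insensitive to truncation at this scale; full scale is exercised in
#: the acceptance suite)
SMALL_WAVE = dict(J=150, t_final=60.0)


@pytest.fixture(scope="session")
def small_wave_kwargs():
    return dict(SMALL_WAVE)


def speed_cached(cache={}):
    """Session-level memo for speed estimates shared between tests."""
    from pclattice.waves import estimate_speed

    def run(theta, q, direction, mu=16.0, p=0.1, **kw):
        key = (theta, q, direction, mu, p, tuple(sorted(kw.items())))
        if key not in cache:
            params = ModelParams(theta=theta, mu=mu, p=p, q=q)
            cache[key] = estimate_speed(params, direction, **kw)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def speed_memo():
    return speed_cached()
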