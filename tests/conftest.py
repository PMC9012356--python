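import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcpratio as m

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def atlas64():
    return m.make_atlas((64, 64, 64), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = m.PhantomSpec(mcp_target_ratio=0.07, noise_sigma=0.0,
                         bias_amplitude=0.0, seed=0)
    return m.make_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    return m.make_phantom(m.PhantomSpec(mcp_target_ratio=0.07, seed=1))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def dice_fn():
    return dice
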