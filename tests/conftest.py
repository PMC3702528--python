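import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_raw():
    """Small complete dataset with a genuine genotype effect on trait 1."""
    from pleioscan import RawDataset

    rng = np.random.default_rng(11)
    n = 60
    g = rng.binomial(2, 0.3, n).astype(float)
    e = rng.standard_normal((n, 3)) @ np.linalg.cholesky(
        np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
    ).T
    Y = e.copy()
    Y[:, 0] += 0.5 * g
    return RawDataset(Y=Y, g=g)
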