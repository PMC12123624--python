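import numpy as np
import pytest

from empff import model as M
from empff.synthetic import DEFAULT_E0


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-element model used across the suite (k=16, L=1, ν=3)."""
    return M.ModelConfig.from_preset("tiny", elements=(1, 8), e0=DEFAULT_E0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return M.init_parameters(tiny_config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
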