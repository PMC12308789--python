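import numpy as np
import pytest

from protomer import (
    SyntheticSpec,
    synthetic_training_table,
    toy_library,
    train,
)


@pytest.fixture(scope="session")
def toy_lib():
    return toy_library()


@pytest.fixture(scope="session")
def small_ranker():
    """A quickly trained energy ranker shared by pipeline-level tests."""
    table = synthetic_training_table(SyntheticSpec(n_systems=60, seed=101))
    return train(table, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
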