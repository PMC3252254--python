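import numpy as np
import pytest

from caudatecut import CaudateCutConfig, PhantomParams, make_phantom
from caudatecut.core import SliceImage


@pytest.fixture(scope="session")
def preset() -> CaudateCutConfig:
    return CaudateCutConfig.phantom_preset()


@pytest.fixture(scope="session")
def params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def subject(params):
    """One deterministic phantom subject shared across tests."""
    return make_phantom(params, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_slice(arr, spacing=(1.0, 1.0)) -> SliceImage:
    return SliceImage(np.asarray(arr, dtype=float), spacing)
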