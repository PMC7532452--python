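import numpy as np
import pytest

from fetomri.phantom import build_phantom
from fetomri.spen import SpenSequenceParams


@pytest.fixture(scope="session")
def spen_params_64() -> SpenSequenceParams:
    return SpenSequenceParams(fov=30.0, matrix=64, n_interleaves=4)


@pytest.fixture(scope="session")
def wt_phantom_64():
    return build_phantom("wildtype", 14.5, (64, 64), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
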