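import numpy as np
import pytest

from gpmsim.dynamics import ModelParams
from gpmsim.genetics import build_inheritance_tensor


@pytest.fixture(scope="session")
def tensor() -> np.ndarray:
    return build_inheritance_tensor()


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()
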