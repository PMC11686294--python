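import numpy as np
import pytest

from _utils import small_space


@pytest.fixture
def space4():
    return small_space(4)


@pytest.fixture
def space2():
    return small_space(2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
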