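import numpy as np
import pytest

from xnafidelity import default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
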