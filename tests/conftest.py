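import numpy as np
import pytest

from groovescan.designs import builtin_design


@pytest.fixture(scope="session")
def design9():
    return builtin_design("dr401_9mer")


@pytest.fixture(scope="session")
def design13():
    return builtin_design("dr401_13mer")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
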