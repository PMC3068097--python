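import numpy as np
import pytest

from paleospruce.fixtures import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110310)
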