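import numpy as np
import pytest

from petkit import variants


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def variant_table():
    return variants.load_variant_table()
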