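import numpy as np
import pytest

from gmvnet.preprocess import encode
from gmvnet.synthetic import generate_cohort, kora_like_preset

PLANTED = ["age", "gfr", "diabetes", "diabetes_duration"]


@pytest.fixture(scope="session")
def kora_preset():
    return kora_like_preset()


@pytest.fixture(scope="session")
def kora_table(kora_preset):
    return generate_cohort(kora_preset, seed=1)


@pytest.fixture(scope="session")
def kora_matrix(kora_table):
    return encode(kora_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
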