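import numpy as np
import pytest

from hftag import stimgen


@pytest.fixture(scope="session")
def bank():
    """Standard 32-token bank at 1 kHz used across stimulus tests."""
    return stimgen.make_syllable_bank(32, 1000.0, seed=1)


@pytest.fixture(scope="session")
def inventory(bank):
    return stimgen.build_sentence_inventory(bank, 12, seed=2)


@pytest.fixture(scope="session")
def structured_64s(bank, inventory):
    return stimgen.build_structured_sequence(bank, inventory, 32, seed=3)


@pytest.fixture(scope="session")
def nonstructured_64s(bank):
    return stimgen.build_nonstructured_sequence(bank, 256, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
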