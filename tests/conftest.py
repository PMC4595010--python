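import numpy as np
import pytest
from hypothesis import settings

from sharpmir import load_fixtures
from sharpmir.simulate import fixture_hairpins

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

ALPHABET = np.array(list("acgu"))


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def hairpins(fixtures):
    return fixture_hairpins(fixtures)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=length)])
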