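import numpy as np
import pytest

from kmercomp.hashes import enumerate_functions


@pytest.fixture(scope="session")
def functions():
    return enumerate_functions()


@pytest.fixture(scope="session")
def balanced(functions):
    return [f for f in functions if f.balanced]


@pytest.fixture(scope="session")
def unbalanced(functions):
    return [f for f in functions if not f.balanced]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
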