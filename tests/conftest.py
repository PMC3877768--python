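import numpy as np
import pytest

from mirseed.seqio import ReferenceSmallRNA


@pytest.fixture
def ref23():
    """A 23-nt reference: yields exactly eight 16-nt seeds."""
    return ReferenceSmallRNA("ref23", "TAGCTTATCAGACTGATGTTGAC", "mature")


@pytest.fixture
def mir21():
    return ReferenceSmallRNA("miR21", "UAGCUUAUCAGACUGAUGUUGA", "mature")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
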