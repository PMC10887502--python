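import numpy as np
import pytest

from mtdemix.preprocess import ReadPair
from mtdemix.simdata import bundled_primers, bundled_reference, bundled_tree


@pytest.fixture(scope="session")
def ref():
    return bundled_reference()


@pytest.fixture(scope="session")
def tree(ref):
    return bundled_tree(ref)


@pytest.fixture(scope="session")
def primers(ref):
    return bundled_primers(ref)


def make_pair(read_id, seq1, qual1, seq2, qual2):
    """ReadPair from sequences and per-base quality lists/ints."""
    if isinstance(qual1, int):
        qual1 = [qual1] * len(seq1)
    if isinstance(qual2, int):
        qual2 = [qual2] * len(seq2)
    return ReadPair(
        read_id,
        seq1,
        np.asarray(qual1, dtype=np.uint8),
        seq2,
        np.asarray(qual2, dtype=np.uint8),
    )
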