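from itertools import product

import numpy as np
import pytest

from lddms import DNA, SequenceSet


@pytest.fixture(scope="session")
def dna():
    return DNA


@pytest.fixture()
def toy_seqs():
    """Two short sequences whose (3,1,0)-motifs are known by hand."""
    return SequenceSet.from_strings(["AAAT", "AATT"])


def random_seqs(rng: np.random.Generator, n: int, m: int) -> SequenceSet:
    """n i.i.d.-uniform DNA sequences of length m."""
    chars = np.array(list("ACGT"))
    return SequenceSet.from_strings(["".join(rng.choice(chars, m)) for _ in range(n)])


def all_lmers(l: int) -> list[str]:
    """All 4^l DNA l-mers in lexicographic order (enumeration oracle)."""
    return ["".join(t) for t in product("ACGT", repeat=l)]
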