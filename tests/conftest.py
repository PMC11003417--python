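import numpy as np
import pytest

from saavbench.chem import DEFAULT_TABLE
from saavbench.digestion import CleavageRule


@pytest.fixture
def table():
    return DEFAULT_TABLE


@pytest.fixture
def loose_rule():
    """No length filtering, one missed cleavage: used by worked examples."""
    return CleavageRule(min_length=1, max_length=1000, max_missed_cleavages=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_peptides(rng, n, min_len=6, max_len=14, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Random tryptic-looking peptides with deliberate near-duplicates.

    Half the peptides are fresh random strings; the other half are copies of
    earlier ones with zero, one or two positions rewritten, so Hamming-0/1/2
    relations actually occur.
    """
    letters = list(alphabet)
    peptides = []
    for _ in range(n):
        if peptides and rng.random() < 0.5:
            seq = list(peptides[int(rng.integers(len(peptides)))])
            for _ in range(int(rng.integers(0, 3))):
                seq[int(rng.integers(len(seq)))] = letters[int(rng.integers(len(letters)))]
            peptides.append("".join(seq))
        else:
            length = int(rng.integers(min_len, max_len + 1))
            peptides.append(
                "".join(letters[int(rng.integers(len(letters)))] for _ in range(length))
            )
    return sorted(set(peptides))
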