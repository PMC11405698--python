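import numpy as np
import pytest

from pdzscan import Alignment, Sequence, SubstitutionMatrix


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture
def toy_alignment():
    return Alignment([Sequence("a", "AC-D"), Sequence("b", "A--D")])


def random_alignment(rng, n_rows, length, gap_rate=0.15, x_rate=0.05):
    """Random gapped alignment used by oracle-equivalence tests."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for i in range(n_rows):
        chars = []
        for _ in range(length):
            u = rng.random()
            if u < gap_rate:
                chars.append("-")
            elif u < gap_rate + x_rate:
                chars.append("X")
            else:
                chars.append(alphabet[rng.integers(20)])
        if all(c == "-" for c in chars):
            chars[rng.integers(length)] = "A"
        rows.append(Sequence(f"r{i}", "".join(chars)))
    return Alignment(rows)
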