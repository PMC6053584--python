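import numpy as np
import pytest

from mitophylogeo.alignment import SequenceAlignment
from mitophylogeo.popmap import PopulationAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_alignment(rng, n, length, alphabet="ACGT"):
    chars = np.array(list(alphabet))
    seqs = ["".join(rng.choice(chars, length)) for _ in range(n)]
    return SequenceAlignment([f"s{i:02d}" for i in range(n)], seqs)


@pytest.fixture
def small_alignment():
    return SequenceAlignment(
        ["a", "b", "c", "d"],
        [
            "AAGACGTTAC",
            "AAGACGTTAC",
            "AGGACGTTAT",
            "AGGACGATAT",
        ],
    )


@pytest.fixture
def two_pop_assignment():
    return PopulationAssignment(
        {"a": "east", "b": "east", "c": "west", "d": "west"}
    )
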