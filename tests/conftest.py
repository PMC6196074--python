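import numpy as np
import pytest

from archroot.matrix import BinaryCharacterMatrix
from archroot.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quartet_tree():
    """Rooted 4-taxon tree with the branch lengths used across likelihood tests."""
    return parse_newick("((A:0.3,B:0.7):0.2,(C:0.5,D:0.9):0.4);")


@pytest.fixture
def small_matrix(rng):
    """Random 4×12 binary matrix (no unknowns)."""
    states = rng.integers(0, 2, size=(4, 12))
    return BinaryCharacterMatrix(list("ABCD"), [f"c{j}" for j in range(12)], states)


def random_matrix(rng, taxa, n_char, p_unknown=0.0):
    states = rng.integers(0, 2, size=(len(taxa), n_char))
    if p_unknown:
        mask = rng.random(states.shape) < p_unknown
        states = np.where(mask, 2, states)
    return BinaryCharacterMatrix(list(taxa), [f"c{j}" for j in range(n_char)], states)
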