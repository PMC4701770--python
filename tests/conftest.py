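import numpy as np
import pytest

from matenet import from_incidence


@pytest.fixture
def two_by_two():
    """The 2x2 network [[1,1],[1,0]] used as a hand-checked example."""
    return from_incidence([[1, 1], [1, 0]])


@pytest.fixture
def sci_example():
    """A male whose two partners have degrees 1 and 3 (row 0 is focal)."""
    return from_incidence(
        [
            [1, 1, 0],
            [0, 1, 0],
            [0, 1, 1],
        ]
    )


@pytest.fixture
def staircase():
    """Perfectly nested 3x3 matrix."""
    return from_incidence([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def block_plus_pair():
    """3x3 complete block plus a separate monogamous pair."""
    inc = np.zeros((4, 4), dtype=int)
    inc[:3, :3] = 1
    inc[3, 3] = 1
    return from_incidence(inc)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
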