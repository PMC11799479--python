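import numpy as np
import pytest

from mutlife import LatticeState, builtin_patterns, place


@pytest.fixture(scope="session")
def patterns():
    return builtin_patterns()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def state_from_pattern(name, size, top_left=None):
    """Empty lattice of the given size with one builtin pattern placed."""
    pat = builtin_patterns()[name]
    if top_left is None:
        top_left = ((size - pat.height) // 2, (size - pat.width) // 2)
    return place(pat, LatticeState.empty(size), top_left)
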