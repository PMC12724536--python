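import numpy as np
import pytest

from mpolyqspr.molgraph import from_edges


def cycle(n):
    return from_edges([(f"v{i}", f"v{(i + 1) % n}") for i in range(n)])


def path(n):
    return from_edges([(f"v{i}", f"v{i + 1}") for i in range(n - 1)])


def star(leaves):
    return from_edges([("hub", f"leaf{i}") for i in range(leaves)])


@pytest.fixture
def p4():
    return path(4)


@pytest.fixture
def c5():
    return cycle(5)


@pytest.fixture
def c6():
    return cycle(6)


@pytest.fixture
def k13():
    return star(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
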