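import numpy as np
import pytest

from sigrefine import GeneUniverse, RankedList


@pytest.fixture
def universe5():
    return GeneUniverse(("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def list5(universe5):
    return RankedList("A", universe5, ("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def make_universe():
    def _make(n, prefix="g"):
        return GeneUniverse(tuple(f"{prefix}{i:04d}" for i in range(n)))

    return _make


@pytest.fixture
def random_list(make_universe):
    """Factory for seeded random ranked lists (optionally over a shared universe)."""

    def _make(n=50, seed=0, id="rand", universe=None):
        universe = universe or make_universe(n)
        rng = np.random.default_rng(seed)
        order = list(universe.genes)
        rng.shuffle(order)
        return RankedList(id, universe, tuple(order))

    return _make
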