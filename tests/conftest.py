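import numpy as np
import pytest

import linrob as lr
from linrob import randomize as rz
from linrob.synth import SyntheticSpec


@pytest.fixture(scope="session")
def toys():
    return lr.toy_lineages()


@pytest.fixture(scope="session")
def tl1(toys):
    return toys["TL1"].lineage


@pytest.fixture(scope="session")
def tl2(toys):
    return toys["TL2"].lineage


@pytest.fixture(scope="session")
def rare3(toys):
    return toys["RARE3"].lineage


@pytest.fixture(scope="session")
def fig16(toys):
    return toys["FIG16"].lineage


@pytest.fixture(scope="session")
def census64():
    return lr.CellTypeCensus({"a": 4, "b": 12, "c": 20, "d": 28})


@pytest.fixture(scope="session")
def lin64(census64):
    """64-terminal, 4-type lineage from free coalescence."""
    return lr.synth_lineage(SyntheticSpec(census=census64, seed=3))


@pytest.fixture(scope="session")
def balanced64(lin64):
    """Same census on a perfectly balanced (depth-6) topology."""
    mode = rz.RandomizationMode(rz.COALESCENT_FIXED_MAXDEPTH, max_depth=6)
    return lr.randomize_lineage(lin64, mode, seed=7)


def random_lineage(n_leaves: int, n_types: int, seed: int):
    """Small random lineage factory used by property tests."""
    rng = np.random.default_rng(seed)
    counts = {}
    for i in range(n_leaves):
        t = f"T{rng.integers(0, n_types)}"
        counts[t] = counts.get(t, 0) + 1
    census = lr.CellTypeCensus(counts)
    return lr.synth_lineage(SyntheticSpec(census=census, seed=int(seed)))
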