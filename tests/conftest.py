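import numpy as np
import pytest

import mycotrack as mt
from mycotrack.benchmark import analyze_simulated


@pytest.fixture(scope="session")
def default_movie():
    """The default synthetic study movie: seed 1, 30 frames, 2 roots."""
    return mt.simulate(mt.SimConfig(seed=1))


@pytest.fixture(scope="session")
def tracked_project(default_movie):
    """The default movie tracked end to end with truth-annotated divisions."""
    stacks, truth = default_movie
    return analyze_simulated(stacks, truth), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def straight_cell():
    """A 40x15 synthetic straight cell: two horizontal edge lines 2w+1 apart
    (w=3) with the interior between them, plus its Sobel-style edge map."""
    edges = np.zeros((15, 40), dtype=bool)
    edges[4, 2:38] = True
    edges[11, 2:38] = True
    edges[4:12, 2] = True
    edges[4:12, 37] = True
    return edges
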