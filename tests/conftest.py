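import numpy as np
import pytest

from mkanc.phylo_io import Chronogram


@pytest.fixture
def two_tip():
    return Chronogram.from_newick("(A:1.0,B:1.0);")


@pytest.fixture
def balanced_four():
    return Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def small_trees():
    """Topologies for exhaustive oracle batteries: cherries, balanced,
    caterpillar, and a hard polytomy, with uneven branch times."""
    return [
        Chronogram.from_newick("(A:0.8,B:1.3);"),
        Chronogram.from_newick("((A:1,B:1):1,(C:0.5,D:1.5):1);"),
        Chronogram.from_newick("(((A:0.4,B:0.9):0.6,C:1.1):0.7,(D:0.8,E:1.2):0.9);"),
        Chronogram.from_newick("((A:1,B:1,C:1):1,(D:0.5,(E:0.7,F:0.3):0.4):1.5);"),
    ]
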