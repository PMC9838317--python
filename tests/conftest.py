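import numpy as np
import pytest

from starling.tree import parse_newick

# The 7-taxon caterpillar of the worked missing-data example: cherries
# (A,B) and (F,G) joined by a backbone carrying C, D, E.  Its A-F internode
# distance is 5; the induced quartet on {A,B,F,G} shrinks it to 2.
CATERPILLAR7 = "(A,B,(C,(D,(E,(F,G)))));"


@pytest.fixture
def caterpillar7():
    return parse_newick(CATERPILLAR7)


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


def random_subsets(labels, rng, size_range=(4, None)):
    lo, hi = size_range
    hi = hi or len(labels)
    size = rng.integers(lo, hi + 1)
    return sorted(rng.choice(sorted(labels), size=size, replace=False))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
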