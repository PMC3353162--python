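import numpy as np
import pytest

from phylodist import parse_newick

QUARTET = "((a:1,b:1):1,(c:1,d:1):1);"
CATERPILLAR = "(((a:1,b:1):1,c:2):1,d:3);"
TWO_LEAF = "(a:1,b:2);"


@pytest.fixture
def quartet():
    """Rooted balanced quartet: total length 6, unrooted form has pendants
    1,1,1,1 and one internal edge of length 2."""
    return parse_newick(QUARTET)


@pytest.fixture
def quartet_unrooted(quartet):
    return quartet.unrooted()


@pytest.fixture
def caterpillar():
    return parse_newick(CATERPILLAR)


@pytest.fixture
def two_leaf():
    return parse_newick(TWO_LEAF)


def max_rel_err(a, b, floor=1e-12):
    """Max elementwise relative error with an absolute floor near zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), floor)))
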