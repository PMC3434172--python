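import pytest

from fasthn import augment_dummy, generate_pair, parse_newick
from fasthn.simulate import SimulationConfig


@pytest.fixture
def fixture_pair():
    """The canonical 3-taxon pair with d = h = 1 and three MAAFs."""
    t1 = augment_dummy(parse_newick("((a,b),c);"))
    t2 = augment_dummy(parse_newick("((a,c),b);"))
    return t1, t2


def make_pair(n, r, seed, augmented=True):
    a, b = generate_pair(SimulationConfig(n_leaves=n, r_moves=r, seed=seed))
    if augmented:
        return augment_dummy(a), augment_dummy(b)
    return a, b
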