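import numpy as np
import pytest

import chronodiv as cd


@pytest.fixture(scope="session")
def cherry_timetree():
    """((A:4,B:4):6,C:10); — the smallest nontrivial chronogram."""
    return cd.timetree_from_newick("((A:4,B:4):6,C:10);")


@pytest.fixture(scope="session")
def bd_timetree():
    """A 20-leaf reconstructed birth-death timetree, fixed seed."""
    return cd.simulate_bd_tree(cd.BDParams(lam=0.15, mu=0.05, n=20), seed=11)


@pytest.fixture(scope="session")
def bd_timetree_50():
    return cd.simulate_bd_tree(cd.BDParams(lam=0.1, mu=0.02, n=50), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
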