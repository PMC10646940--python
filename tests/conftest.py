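import numpy as np
import pytest

from cgcage import build_cage, get_topology, make_block, optimise_cage


def make_cage(topology, combo, torsion_state="on"):
    arity = {"ditopic": 2, "tritopic": 3, "tetratopic": 4}
    blocks = {arity[k]: make_block(k, a) for k, a in combo.items()}
    return build_cage(get_topology(topology), blocks, torsion_state=torsion_state)


@pytest.fixture(scope="session")
def tri4di6_exemplar():
    """Optimised stable Tri4Di6 cage (tritopic 120, ditopic 125, restricted)."""
    cage = make_cage("Tri4Di6", {"ditopic": 125.0, "tritopic": 120.0})
    return cage, optimise_cage(cage, seed=7)


@pytest.fixture(scope="session")
def tet6di12_exemplar():
    """Optimised stable Tet6Di12 cage (square-planar tetratopic, ditopic 135)."""
    cage = make_cage("Tet6Di12", {"ditopic": 135.0, "tetratopic": 90.0})
    return cage, optimise_cage(cage, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
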