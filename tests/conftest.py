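import numpy as np
import pytest

import beringia as b


@pytest.fixture(scope="session")
def backbone():
    """The genus-level Polyommatus backbone fixture (chronogram + codings)."""
    return b.fixture_polyommatus()


@pytest.fixture(scope="session")
def backbone_dec(backbone):
    """Fitted DEC reconstruction on the backbone (shared across tests)."""
    model = b.DECModel(backbone.chronogram, backbone.area_codings)
    return model, model.fit()


@pytest.fixture()
def small_tree():
    """((A:1,B:1):1,C:2); in Ma."""
    return b.read_newick("((A:1,B:1):1,C:2);", unit="Ma")


def random_trees(n_trees, n_tips, seed=0, unit="Ma"):
    """Deterministic batch of simulated chronograms."""
    out = []
    for i in range(n_trees):
        chrono, phylo = b.sim_tree(n_tips, seed=seed + i)
        out.append(chrono if unit == "Ma" else phylo)
    return out
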