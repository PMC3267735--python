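import numpy as np
import pytest

from voxconn import (make_roi, select_subregion, simulate_session,
                     preprocess_session, EffectSpec, FunctionalGraph)


@pytest.fixture(scope="session")
def roi200():
    return make_roi(200, "slab", seed=1)


@pytest.fixture(scope="session")
def roi_small():
    return make_roi(30, "blob", seed=2)


@pytest.fixture(scope="session")
def null_session(roi200):
    """One preprocessed null resting-state session (shared, read-only)."""
    bold, nuis = simulate_session(roi200, seed=3)
    clean = preprocess_session(bold, nuis)
    return bold, nuis, clean


def graph_from_edges(n, edges, T=None):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return FunctionalGraph(adjacency=adj, node_ids=np.arange(n), threshold_T=T)


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return graph_from_edges(3, [(0, 1), (1, 2)])
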