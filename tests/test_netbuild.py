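import numpy as np
import pytest

from voxconn import (CleanSeries, SyncMatrix, correlation_matrix,
                     group_common_threshold, largest_component,
                     restrict_to_largest, scan_tmax, threshold_graph)
from oracles import components_oracle, random_adjacency


def sync(values):
    return SyncMatrix(values=np.asarray(values, float))


def test_correlation_matrix_definitional():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 20))
    M = correlation_matrix(CleanSeries(x, 1.8))
    xc = x - x.mean(axis=1, keepdims=True)
    for i in range(5):
        for j in range(5):
            ref = (xc[i] @ xc[j]) / np.sqrt((xc[i] @ xc[i]) * (xc[j] @ xc[j]))
            assert M.values[i, j] == pytest.approx(ref, abs=1e-12)


def test_correlation_matrix_special_rows():
    t = np.linspace(0, 2 * np.pi, 101)[:-1]
    x = np.vstack([np.sin(t), np.cos(t), np.sin(t)])
    M = correlation_matrix(CleanSeries(x, 1.0))
    assert abs(M.values[0, 1]) < 1e-6          # orthogonal over full periods
    assert M.values[0, 2] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        correlation_matrix(CleanSeries(np.vstack([t, np.ones_like(t)]), 1.0))


def test_threshold_is_strict_and_positive_only():
    m = np.eye(3)
    m[0, 1] = m[1, 0] = 0.5
    m[0, 2] = m[2, 0] = 0.2
    m[1, 2] = m[2, 1] = 0.4
    G = threshold_graph(sync(m), 0.35)
    assert sorted(map(tuple, G.edge_list())) == [(0, 1), (1, 2)]
    assert threshold_graph(sync(m), 0.6).n_edges == 0
    # boundary: equality does not create an edge
    assert threshold_graph(sync(m), 0.5).n_edges == 0 or \
        (0, 1) not in set(map(tuple, threshold_graph(sync(m), 0.5).edge_list()))
    assert not threshold_graph(sync(m), 0.5).adjacency[0, 1]
    # negative correlations never form edges
    m2 = np.eye(2)
    m2[0, 1] = m2[1, 0] = -0.9
    assert threshold_graph(sync(m2), 0.1).n_edges == 0
    with pytest.raises(ValueError):
        threshold_graph(sync(m), 0.0)


def test_largest_component_fraction_and_ties():
    from conftest import graph_from_edges
    G = graph_from_edges(5, [(0, 1), (1, 2), (3, 4)])
    nodes, frac = largest_component(G)
    assert frac == pytest.approx(0.6)
    assert nodes.tolist() == [0, 1, 2]
    # tie between {0,1} and {2,3}: component containing node 0 wins
    G2 = graph_from_edges(4, [(0, 1), (2, 3)])
    nodes2, frac2 = largest_component(G2)
    assert frac2 == 0.5 and nodes2.tolist() == [0, 1]


def test_components_match_warshall_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        adj = random_adjacency(20, 0.12, rng)
        from voxconn import FunctionalGraph
        G = FunctionalGraph(adjacency=np.array(adj), node_ids=np.arange(20))
        labels = components_oracle(adj)
        nodes, frac = largest_component(G)
        sizes = np.bincount(labels)
        assert frac == pytest.approx(sizes.max() / 20)
        assert len(nodes) == sizes.max()


def test_scan_tmax_four_node_example():
    """Constructed 4-node matrix: the scan must stop exactly at 0.298, the
    last grid point at which the 0.30 edge still exists (strict >)."""
    m = np.eye(4)
    m[0, 1] = m[1, 0] = 0.9
    m[1, 2] = m[2, 1] = 0.9
    m[2, 3] = m[3, 2] = 0.30
    m[0, 2] = m[2, 0] = m[0, 3] = m[3, 0] = m[1, 3] = m[3, 1] = 0.05
    res = scan_tmax(sync(m), criterion=0.95)
    assert res.T_max == pytest.approx(0.298)
    assert res.largest_component_fraction[-1] == pytest.approx(0.75)


def test_scan_tmax_complete_matrix_exhausts_grid():
    m = np.full((5, 5), 0.9)
    np.fill_diagonal(m, 1.0)
    res = scan_tmax(sync(m))
    assert res.T_max == pytest.approx(0.898)


def test_scan_tmax_weak_data_errors():
    m = np.eye(4)
    with pytest.raises(ValueError, match="weakly connected"):
        scan_tmax(sync(m))


def test_scan_fraction_non_increasing(null_session):
    _, _, clean = null_session
    M = correlation_matrix(clean)
    res = scan_tmax(M, full_grid=True, T_stop=0.9)
    frac = res.largest_component_fraction
    assert np.all(np.diff(frac) <= 1e-12)
    # edge count also non-increasing in T
    edges = [threshold_graph(M, T).n_edges for T in (0.2, 0.3, 0.4, 0.5)]
    assert all(a >= b for a, b in zip(edges, edges[1:]))


def test_threshold_below_min_gives_complete_graph():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(6, 50))
    M = correlation_matrix(CleanSeries(x, 1.0))
    off = M.values[~np.eye(6, dtype=bool)]
    T = max(1e-6, off.min() - 0.01)
    if 0 < T < 1:
        G = threshold_graph(M, T) if off.min() > 0 else None
        if G is not None:
            assert G.n_edges == 15


def test_group_common_threshold():
    assert group_common_threshold([0.352, 0.40, 0.39]) == pytest.approx(0.352)
    assert group_common_threshold([0.2]) == 0.2
    assert group_common_threshold([0.4, 0.3, 0.35]) == \
        group_common_threshold([0.3, 0.35, 0.4])
    with pytest.raises(ValueError):
        group_common_threshold([])


def test_restrict_to_largest():
    from conftest import graph_from_edges
    G = graph_from_edges(4, [(0, 1), (1, 2)])   # node 3 isolated
    sub = restrict_to_largest(G)
    assert sub.n_nodes == 3
    assert sub.node_ids.tolist() == [0, 1, 2]
    assert sub.n_edges == 2
    connected = graph_from_edges(3, [(0, 1), (1, 2)])
    same = restrict_to_largest(connected)
    assert same.n_nodes == 3 and same.n_edges == 2


def test_sync_matrix_validation():
    bad = np.array([[1.0, 0.5], [0.4, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        SyncMatrix(values=bad)
    with pytest.raises(ValueError):
        SyncMatrix(values=np.array([[1.0, 1.5], [1.5, 1.0]]))
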