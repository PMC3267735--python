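"""Synchronization matrices and threshold-scanned functional graphs.

An N x N zero-lag Pearson correlation matrix over ROI voxels is turned into
an undirected simple graph by keeping edges where r > T (strict; negative
correlations never form edges).  The adaptive threshold scan raises T from
0.1 in steps of 0.002 until the giant connected component drops below 95 %
of the nodes, yielding a per-dataset T_max; group analyses use the minimum
T_max over all datasets so every graph is evaluated at one common threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SyncMatrix", "FunctionalGraph", "ThresholdScanResult",
    "correlation_matrix", "threshold_graph", "largest_component",
    "scan_tmax", "group_common_threshold", "restrict_to_largest",
]


@dataclass
class SyncMatrix:
    """Symmetric matrix of zero-lag Pearson correlations between voxels."""

    values: np.ndarray
    roi: object = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("synchronization matrix must be symmetric")
        off = v[~np.eye(len(v), dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class FunctionalGraph:
    """Undirected simple graph over (a subset of) ROI voxels.

    ``node_ids`` maps graph node positions to original voxel indices so that
    metric maps stay aligned to the ROI after restriction to the largest
    component.
    """

    adjacency: np.ndarray                  # dense boolean, symmetric
    node_ids: np.ndarray                   # original voxel index per node
    threshold_T: float | None = None
    component_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        if len(self.node_ids) != a.shape[0]:
            raise ValueError("node_ids length must match adjacency")
        if self.component_labels is None:
            _, labels = connected_components(csr_matrix(a), directed=False)
            self.component_labels = labels

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(E, 2) array of node-position pairs i < j."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return np.column_stack([iu[0][mask], iu[1][mask]])

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass
class ThresholdScanResult:
    T_grid: np.ndarray
    largest_component_fraction: np.ndarray
    T_max: float
    criterion: float = 0.95

    def __post_init__(self):
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.largest_component_fraction = np.asarray(
            self.largest_component_fraction, dtype=float)


def correlation_matrix(ts) -> SyncMatrix:
    """All-pairs zero-lag Pearson correlation of voxel time series."""
    x = np.asarray(ts.data, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant time series at voxels {bad}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return SyncMatrix(values=r, roi=getattr(ts, "roi", None))


def threshold_graph(M: SyncMatrix, T: float) -> FunctionalGraph:
    """Binarize the synchronization matrix: edge iff r > T (strict)."""
    if not 0 < T < 1:
        raise ValueError("T must lie in (0, 1)")
    a = M.values > T
    np.fill_diagonal(a, False)
    return FunctionalGraph(adjacency=a, node_ids=np.arange(M.n_nodes),
                           threshold_T=float(T))


def largest_component(G: FunctionalGraph) -> tuple[np.ndarray, float]:
    """Node positions of the largest connected component and its fraction.

    Size ties are broken in favour of the component containing the lowest
    node index.
    """
    labels = G.component_labels
    sizes = np.bincount(labels)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        first_node = [np.flatnonzero(labels == b)[0] for b in best]
        best = [best[int(np.argmin(first_node))]]
    nodes = np.flatnonzero(labels == best[0])
    return nodes, len(nodes) / G.n_nodes


def _giant_fraction(values: np.ndarray, T: float) -> float:
    a = values > T
    np.fill_diagonal(a, False)
    _, labels = connected_components(csr_matrix(a), directed=False)
    return np.bincount(labels).max() / len(values)


def scan_tmax(M: SyncMatrix, T0: float = 0.1, step: float = 0.002,
              criterion: float = 0.95, full_grid: bool = False,
              T_stop: float = 1.0) -> ThresholdScanResult:
    """Adaptive percolation threshold scan.

    Raise T from ``T0`` in steps of ``step``; T_max is the largest grid
    value at which the giant component still holds at least ``criterion``
    of all nodes.  By default the scan stops at the first failing grid
    point ("until" semantics); ``full_grid`` continues to ``T_stop`` for
    plotting the whole trajectory.
    """
    if not 0 < T0 < 1 or step <= 0:
        raise ValueError("need 0 < T0 < 1 and step > 0")
    grid, fractions = [], []
    T_max = None
    k = 0
    while True:
        T = T0 + k * step
        if T >= T_stop or T >= 1.0:
            break
        frac = _giant_fraction(M.values, T)
        grid.append(T)
        fractions.append(frac)
        if frac >= criterion:
            T_max = T
        else:
            if T_max is None:
                raise ValueError(
                    f"largest component holds {frac:.3f} < {criterion} of nodes "
                    f"already at T0={T0}: data too weakly connected")
            if not full_grid:
                break
        k += 1
    if T_max is None:
        raise ValueError("threshold scan produced no admissible T_max")
    return ThresholdScanResult(T_grid=np.array(grid),
                               largest_component_fraction=np.array(fractions),
                               T_max=float(T_max), criterion=criterion)


def group_common_threshold(t_maxes) -> float:
    """Common group threshold: the minimum per-dataset T_max."""
    t_maxes = [float(t) for t in t_maxes]
    if not t_maxes:
        raise ValueError("need at least one T_max")
    return min(t_maxes)


def restrict_to_largest(G: FunctionalGraph) -> FunctionalGraph:
    """Induced subgraph on the largest connected component.

    Dropped voxels are recoverable by comparing ``node_ids`` with the parent
    graph; map construction treats them as missing.
    """
    nodes, _ = largest_component(G)
    sub = G.adjacency[np.ix_(nodes, nodes)]
    return FunctionalGraph(adjacency=sub, node_ids=G.node_ids[nodes],
                           threshold_T=G.threshold_T)
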