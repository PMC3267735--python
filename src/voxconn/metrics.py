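"""Nodal and global graph metrics: degree, clustering, path length and the
small-world coefficients gamma, lambda, sigma.

Definitions are the standard binary-graph ones: K_i is the neighbour count,
C_i the Watts-Strogatz local clustering (realized fraction of the
k_i(k_i-1)/2 possible neighbour pairs; 0 by convention for k_i < 2), and
L_i the mean unweighted shortest-path distance from node i to every other
node of a connected graph.  Global K, C, L are unweighted means of the
nodal values over the largest component; gamma = C/C_rand, lambda =
L/L_rand against a degree-preserving null, and sigma = gamma/lambda is the
small-worldness ratio (sigma >> 1: segregated *and* integrated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import FunctionalGraph

__all__ = [
    "NodalMetrics", "GlobalMetrics",
    "nodal_degree", "nodal_clustering", "nodal_path_length",
    "compute_nodal_metrics", "global_metrics",
]


@dataclass
class NodalMetrics:
    node_ids: np.ndarray
    K: np.ndarray
    C: np.ndarray
    L: np.ndarray | None = None


@dataclass
class GlobalMetrics:
    K: float
    C: float
    L: float
    C_rand: float | None = None
    L_rand: float | None = None

    @property
    def gamma(self) -> float:
        return self.C / self.C_rand if self.C_rand else np.nan

    @property
    def lam(self) -> float:
        return self.L / self.L_rand if self.L_rand else np.nan

    @property
    def sigma(self) -> float:
        g, l = self.gamma, self.lam
        return g / l if np.isfinite(g) and np.isfinite(l) and l != 0 else np.nan


def nodal_degree(G: FunctionalGraph) -> np.ndarray:
    """K_i: number of direct neighbours of each node."""
    return G.degrees()


def nodal_clustering(G: FunctionalGraph) -> np.ndarray:
    """C_i: edges among the neighbours of i over k_i(k_i-1)/2; 0 if k_i < 2.

    Triangle counts come from diag(A^3)/2 on the dense adjacency, which for
    the few-hundred-node graphs used here is faster than per-node
    neighbourhood extraction.
    """
    a = G.adjacency.astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c


def nodal_path_length(G: FunctionalGraph) -> np.ndarray:
    """L_i: mean unweighted shortest-path distance from i to all j != i.

    Requires a connected graph (restrict to the largest component first).
    """
    n = G.n_nodes
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = shortest_path(csr_matrix(G.adjacency), method="D", unweighted=True,
                      directed=False)
    if np.isinf(d).any():
        raise ValueError("graph is disconnected; restrict to the largest "
                         "component before computing path lengths")
    return d.sum(axis=1) / (n - 1)


def compute_nodal_metrics(G: FunctionalGraph, with_path_length: bool = True
                          ) -> NodalMetrics:
    L = nodal_path_length(G) if with_path_length else None
    return NodalMetrics(node_ids=G.node_ids.copy(), K=nodal_degree(G),
                        C=nodal_clustering(G), L=L)


def global_metrics(G: FunctionalGraph, null_summary=None) -> GlobalMetrics:
    """Global means over a connected graph, optionally null-normalized.

    ``null_summary`` is any object exposing ``C_rand`` and ``L_rand``
    (an ensemble summary from the nulls module, or the analytic pair).
    """
    nm = compute_nodal_metrics(G)
    gm = GlobalMetrics(K=float(nm.K.mean()), C=float(nm.C.mean()),
                       L=float(nm.L.mean()))
    if null_summary is not None:
        gm.C_rand = float(null_summary.C_rand)
        gm.L_rand = float(null_summary.L_rand)
    return gm
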