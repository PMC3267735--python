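"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain-Python loops over adjacency
matrices, Floyd-Warshall, Warshall transitive closure, direct triangle
enumeration.  None of it shares code with the package.
"""

import numpy as np


def degree_oracle(adj):
    """Row sums of the adjacency matrix, counted entry by entry."""
    n = len(adj)
    return [sum(1 for j in range(n) if adj[i][j]) for i in range(n)]


def clustering_oracle(adj):
    """Watts-Strogatz local clustering by explicit neighbour-pair counting."""
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a]][nbrs[b]]:
                    links += 1
        out.append(links / (k * (k - 1) / 2))
    return out


def floyd_warshall_oracle(adj):
    """All-pairs unweighted shortest paths via Floyd-Warshall."""
    n = len(adj)
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            for j in range(n):
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return d


def path_length_oracle(adj):
    """Per-node mean shortest-path distance (requires connected graph)."""
    d = floyd_warshall_oracle(adj)
    n = len(adj)
    return [sum(d[i][j] for j in range(n) if j != i) / (n - 1)
            for i in range(n)]


def components_oracle(adj):
    """Connected components via Warshall transitive closure."""
    n = len(adj)
    reach = [[bool(adj[i][j]) or i == j for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    labels = [-1] * n
    cur = 0
    for i in range(n):
        if labels[i] == -1:
            for j in range(n):
                if reach[i][j]:
                    labels[j] = cur
            cur += 1
    return labels


def normal_equations_residual(y, X):
    """OLS residual via explicit normal equations (X'X)^-1 X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def random_adjacency(n, p, rng):
    """Simple undirected random graph as a nested-list adjacency matrix."""
    a = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                a[i][j] = a[j][i] = True
    return a
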