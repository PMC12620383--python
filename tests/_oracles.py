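"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here deliberately avoids the code paths of the implementation:
dense eigendecomposition instead of power iteration, hand-rolled BFS/DFS
path enumeration instead of networkx's centrality algorithms, double loops
instead of sorted-sequence identities.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def clustering_oracle(G, v, scale=10.0) -> float:
    nbrs = list(G.neighbors(v))
    if len(nbrs) < 2:
        return 0.0
    pairs = list(combinations(nbrs, 2))
    closed = sum(1 for a, b in pairs if G.has_edge(a, b))
    return closed / len(pairs) * scale


def eigen_oracle(A: np.ndarray):
    """Leading eigenpair by dense symmetric eigendecomposition.

    Returns (lambda_1, gap, |v_1|); for degenerate leading eigenvalues the
    vector is an arbitrary element of the eigenspace.
    """
    vals, vecs = np.linalg.eigh(A)
    lam = vals[-1]
    gap = lam - vals[-2] if len(vals) > 1 else np.inf
    return lam, gap, np.abs(vecs[:, -1])


def bfs_distances(G, source):
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in G.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def closeness_oracle(G, v, scale=10.0) -> float:
    n = G.number_of_nodes()
    dist = bfs_distances(G, v)
    r = len(dist)  # reachable set, including v
    if r < 2 or n < 2:
        return 0.0
    total = sum(dist.values())
    return (r - 1) / total * (r - 1) / (n - 1) * scale


def _all_simple_paths(adj, s, t):
    paths = []
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + (nb,)))
    return paths


def betweenness_oracle(G, scale=10.0) -> dict:
    """Betweenness via exhaustive simple-path enumeration per pair."""
    nodes = list(G)
    n = len(nodes)
    adj = {v: list(G.neighbors(v)) for v in nodes}
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        sigma = len(sp)
        for v in nodes:
            if v == s or v == t:
                continue
            through = sum(1 for p in sp if v in p)
            bc[v] += through / sigma
    denom = (n - 1) * (n - 2) / 2
    if denom > 0:
        bc = {v: b / denom * scale for v, b in bc.items()}
    return bc


def gini_oracle(values, scale=1.0) -> float:
    v = np.asarray(values, dtype=float)
    n = len(v)
    total = sum(abs(a - b) for a in v for b in v)
    vbar = v.mean()
    if vbar == 0:
        return 0.0
    return total / (2 * n**2 * vbar) * scale


def hc1_oracle(X, y):
    """Explicit matrix-algebra OLS + HC1 sandwich."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    bread = np.linalg.inv(X.T @ X)
    beta = bread @ X.T @ y
    e = y - X @ beta
    meat = X.T @ np.diag(e**2) @ X
    cov = n / (n - k) * bread @ meat @ bread
    return beta, np.sqrt(np.diag(cov))


def holm_oracle(pvals, alpha=0.05):
    """Literal step-down Holm: test p_(j) against alpha/(m-j+1) in order."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
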