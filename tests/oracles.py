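"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python BFS, exhaustive
enumeration, direct moment formulas) and shares no code with the package
implementation it checks.
"""

from collections import deque
from itertools import combinations

import math


def bfs_distances(adj, source):
    """Hop distances from source on a 0/1 adjacency (list-of-lists ok)."""
    n = len(adj)
    dist = [math.inf] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] == math.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_pairs(adj):
    return [bfs_distances(adj, s) for s in range(len(adj))]


def oracle_degree(adj):
    return [sum(row) for row in adj]


def oracle_clustering(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(adj[u][v] for u, v in combinations(nbrs, 2))
        out.append(2.0 * links / (k * (k - 1)))
    return out


def oracle_global_efficiency(adj):
    n = len(adj)
    if n < 2:
        return 0.0
    d = all_pairs(adj)
    total = sum(
        1.0 / d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and d[i][j] != math.inf
    )
    return total / (n * (n - 1))


def oracle_local_efficiency(adj):
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[adj[u][v] for v in nbrs] for u in nbrs]
        out.append(oracle_global_efficiency(sub))
    return out


def oracle_cpl(adj):
    """(mean distance over reachable ordered pairs, n unreachable)."""
    n = len(adj)
    d = all_pairs(adj)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] != math.inf]
    unreachable = n * (n - 1) - len(finite)
    if not finite:
        return None, unreachable
    return sum(finite) / len(finite), unreachable


def oracle_triangles(matrix, indices, thr, tol=1e-12):
    """Exhaustive triple enumeration with per-triple Heron area."""
    admitted = []
    n_invalid = 0
    for i, j, k in combinations(sorted(indices), 3):
        a, b, c = matrix[i][j], matrix[i][k], matrix[j][k]
        if a <= 0 or b <= 0 or c <= 0:
            continue
        s = (a + b + c) / 2.0
        rad = s * (s - a) * (s - b) * (s - c)
        if rad <= 0:
            n_invalid += 1
            continue
        area = math.sqrt(rad)
        if area >= thr - tol:
            admitted.append(((i, j, k), area))
    return admitted, n_invalid


def exact_ranksum_pvalue(x, y):
    """Two-sided p of the rank-sum by exhaustive permutation of group labels."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _rank(pooled)
    observed = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        stat = sum(ranks[i] for i in combo)
        total += 1
        if abs(stat - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def _rank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def oracle_bh(pvalues):
    """Step-up Benjamini-Hochberg by direct definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
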