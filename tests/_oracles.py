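"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (hand-coded
BFS, O(n²) pair counting, exhaustive tail sums, dense eliminations) and never
calls into the package, so tests compare two independent routes to the same
quantity.
"""

from collections import deque
from itertools import combinations
from math import comb, exp, log

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Hand-coded breadth-first search distances from one node."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def graph_to_adj(graph) -> dict:
    return {n: sorted(graph.neighbors(n)) for n in graph.nodes}


def oracle_closest(adj, targets, genes):
    vals = []
    for t in sorted(targets):
        d = bfs_distances(adj, t)
        finite = [d[g] for g in genes if g in d]
        if finite:
            vals.append(min(finite))
    return sum(vals) / len(vals)


def oracle_shortest(adj, targets, genes):
    vals = []
    for t in sorted(targets):
        d = bfs_distances(adj, t)
        vals.extend(d[g] for g in genes if g in d)
    return sum(vals) / len(vals)


def oracle_kernel(adj, targets, genes):
    terms = []
    for g in sorted(genes):
        inner = 0.0
        for t in targets:
            d = bfs_distances(adj, t)
            if g in d:
                inner += exp(-(d[g] + 1))
        inner /= len(targets)
        if inner > 0:
            terms.append(-log(inner))
    return sum(terms) / len(terms)


def oracle_centre(adj, targets, genes):
    def closeness(g):
        d = bfs_distances(adj, g)
        total = sum(d.values())
        return (len(d) - 1) / total if total else 0.0

    best = None
    for g in sorted(genes):
        c = closeness(g)
        if best is None or c > best[1]:
            best = (g, c)
    d = bfs_distances(adj, best[0])
    vals = [d[t] for t in sorted(targets) if t in d]
    return sum(vals) / len(vals)


def oracle_separation(adj, targets, genes):
    def closest_between(A, B):
        mins = []
        for a in sorted(A):
            d = bfs_distances(adj, a)
            finite = [d[b] for b in B if b in d]
            if finite:
                mins.append(min(finite))
        return mins

    def closest_within(S):
        if len(S) < 2:
            return 0.0
        mins = []
        for s in sorted(S):
            d = bfs_distances(adj, s)
            finite = [d[o] for o in S if o != s and o in d]
            if finite:
                mins.append(min(finite))
        return sum(mins) / len(mins) if mins else 0.0

    tg = closest_between(targets, genes)
    gt = closest_between(genes, targets)
    d_tg = (sum(tg) + sum(gt)) / (len(tg) + len(gt))
    return d_tg - (closest_within(targets) + closest_within(genes)) / 2


def oracle_rwr_linear(graph, p0: np.ndarray, r: float) -> np.ndarray:
    """Dense solve of the restart-walk fixed point, built from scratch."""
    order = sorted(graph.nodes)
    n = len(order)
    A = np.zeros((n, n))
    idx = {node: i for i, node in enumerate(order)}
    for u, v in graph.edges:
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    col = A.sum(axis=0)
    W = np.divide(A, col, out=np.zeros_like(A), where=col > 0)
    return r * np.linalg.solve(np.eye(n) - (1 - r) * W.T, p0)


def oracle_auroc(scores, labels) -> float:
    """O(n²) pair counting with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_fisher_greater(both, a_only, b_only, neither) -> float:
    """Upper hypergeometric tail by exhaustive summation."""
    n = both + a_only + b_only + neither
    K = both + a_only        # documents with term A
    m = both + b_only        # documents with term B
    hi = min(K, m)
    total = comb(n, m)
    return sum(comb(K, k) * comb(n - K, m - k) for k in range(both, hi + 1)) / total


def oracle_mwu_exact(x, y) -> float:
    """Two-sided permutation enumeration of the U statistic (midranks)."""
    pooled = list(x) + list(y)
    nx, ny = len(x), len(y)
    ranks = _midranks(pooled)
    centre = nx * ny / 2.0
    u_obs = sum(ranks[:nx]) - nx * (nx + 1) / 2.0
    observed = abs(u_obs - centre)
    count = total = 0
    for subset in combinations(range(nx + ny), nx):
        u = sum(ranks[i] for i in subset) - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - centre) >= observed - 1e-12:
            count += 1
    return count / total


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def enumerate_ngrams(word: str, n_min: int, n_max: int) -> list:
    padded = "<" + word + ">"
    out = []
    for n in range(n_min, n_max + 1):
        for i in range(len(padded)):
            sub = padded[i : i + n]
            if len(sub) == n:
                out.append(sub)
    return out
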