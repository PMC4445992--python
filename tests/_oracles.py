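"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — nested scalar loops, exhaustive
enumeration, grid searches — and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def objective_loops(W, R, T, D, A_p, A_f, A_c, beta=1.0):
    """Scalar-summation objective: density term over (i, j, k), functional
    term over (i, j, m), minus the two Frobenius norms."""
    n = T.shape[0]
    density = 0.0
    for i in range(n):
        for j in range(n):
            triangle = 0.0
            for k in range(n):
                triangle += W[i, k] * W[j, k] * T[i, k] * T[j, k]
            density += D[i, j] * W[i, j] * triangle
    functional = 0.0
    A = (A_p, A_f, A_c)
    for i in range(n):
        for j in range(n):
            for m in range(3):
                functional += W[i, j] * A[m][i, j] * R[i, m]
    frob_w = sum(W[i, j] ** 2 for i in range(n) for j in range(n))
    frob_r = sum(R[i, m] ** 2 for i in range(n) for m in range(3))
    return density + beta * functional - frob_w - frob_r


def grid_argmax_w(coefficient, step=1e-3):
    """Brute-force maximizer of the per-entry concave subproblem
    J(w) = −w² + c·w over a [0, 1] grid."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    values = -grid * grid + coefficient * grid
    return float(grid[int(np.argmax(values))])


def central_difference_gradient(fun, x, eps=1e-6):
    """Central finite differences of a scalar function of a vector."""
    g = np.zeros_like(x, dtype=float)
    for m in range(x.size):
        hi = x.copy()
        lo = x.copy()
        hi[m] += eps
        lo[m] -= eps
        g[m] = (fun(hi) - fun(lo)) / (2 * eps)
    return g


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(n, edges):
    """Connected components (as frozensets of node indices) of an undirected
    graph given by unordered index pairs."""
    uf = UnionFind(n)
    for i, j in edges:
        uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for v in range(n):
        groups.setdefault(uf.find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


def brute_force_mmr(rate_matrix):
    """Best total weight over every one-to-one matching of rows (reference)
    to columns (predictions), divided by the number of rows. Feasible only
    for small instances."""
    n_ref, n_pred = rate_matrix.shape
    k = min(n_ref, n_pred)
    best = 0.0
    for rows in combinations(range(n_ref), k):
        for cols in permutations(range(n_pred), k):
            total = sum(rate_matrix[r, c] for r, c in zip(rows, cols))
            best = max(best, total)
    return best / n_ref


def pairwise_match_counts(predicted, reference, threshold, rate):
    """Exhaustive TP/FP/FN via per-pair rate evaluation."""
    tp = sum(
        1 for p in predicted if any(rate(p, r) >= threshold for r in reference)
    )
    fp = len(predicted) - tp
    matched_refs = sum(
        1 for r in reference if any(rate(p, r) >= threshold for p in predicted)
    )
    fn = len(reference) - matched_refs
    return tp, fp, fn, matched_refs
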