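"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations (triple-loop Floyd–Warshall, exhaustive
triangle enumeration, full set-partition enumeration, literal step-up
multiplicity formulas) kept separate from the package so agreement is a real
cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def bf_distances(A) -> np.ndarray:
    """Floyd–Warshall shortest paths on a binary adjacency matrix."""
    A = np.asarray(A)
    n = A.shape[0]
    D = np.full((n, n), math.inf)
    for i in range(n):
        D[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] > 0:
                D[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def bf_nodal_global_efficiency(A) -> np.ndarray:
    A = np.asarray(A)
    n = A.shape[0]
    D = bf_distances(A)
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and math.isfinite(D[i, j]):
                s += 1.0 / D[i, j]
        out[i] = s / (n - 1)
    return out


def bf_average_global_efficiency(A) -> float:
    return float(np.mean(bf_nodal_global_efficiency(A)))


def bf_nodal_local_efficiency(A) -> np.ndarray:
    A = np.asarray(A)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j] > 0]
        if len(nb) < 2:
            out[i] = 0.0
        else:
            sub = A[np.ix_(nb, nb)]
            out[i] = bf_average_global_efficiency(sub)
    return out


def bf_transitivity(A) -> float:
    A = np.asarray(A)
    n = A.shape[0]
    triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if A[i, j] and A[j, k] and A[i, k]:
                    triangles += 1
    triples = 0
    for i in range(n):
        k_i = int(A[i].sum())
        triples += k_i * (k_i - 1)
    if triples == 0:
        return 0.0
    return 6.0 * triangles / triples


def bf_strength(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    return np.array([sum(W[i, j] for j in range(n)) for i in range(n)])


# ---------------------------------------------------------------------------
# exhaustive modularity optimum
# ---------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def literal_modularity(W, membership, gamma=1.0) -> float:
    """Double-loop literal of Q = (1/2m) sum_ij [w_ij - g k_i k_j/2m] d(ci,cj)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    two_m = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += W[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def exhaustive_best_modularity(W, gamma=1.0) -> float:
    """Maximum Q over every partition of the nodes (n <= ~9)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    best = -math.inf
    memb = np.empty(n, dtype=int)
    for part in set_partitions(range(n)):
        for c, block in enumerate(part):
            for node in block:
                memb[node] = c
        q = literal_modularity(W, memb, gamma)
        if q > best:
            best = q
    return best


# ---------------------------------------------------------------------------
# literal step-up multiplicity adjustments
# ---------------------------------------------------------------------------

def literal_bh(p):
    """Benjamini–Hochberg: adj_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank0, idx in enumerate(order):
        best = math.inf
        for j0 in range(rank0, m):
            cand = m * p[order[j0]] / (j0 + 1)
            best = min(best, cand)
        adj_sorted[rank0] = min(best, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def literal_hochberg(p):
    """Hochberg: adj_(i) = min_{j>=i} (m - j + 1) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank0, idx in enumerate(order):
        best = math.inf
        for j0 in range(rank0, m):
            cand = (m - (j0 + 1) + 1) * p[order[j0]]
            best = min(best, cand)
        adj_sorted[rank0] = min(best, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def random_binary_graph(rng, n, p=None):
    """Random undirected simple graph as a 0/1 matrix."""
    if p is None:
        p = rng.uniform(0.2, 0.8)
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return A


def random_weighted_graph(rng, n, p=None):
    A = random_binary_graph(rng, n, p)
    Wt = rng.uniform(0.05, 1.0, size=(n, n))
    Wt = np.triu(Wt, 1)
    Wt = Wt + Wt.T
    return A * Wt
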