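"""Binary and weighted graph measures, nodal and global.

Efficiency measures run on the binarized networks across the density sweep;
strength runs on the weighted network before binarization.  Conventions for
degenerate cases follow the standard graph-theory formulary for brain
networks: disconnected pairs contribute 0 (inverse-distance convention) and
the local efficiency of a node with fewer than 2 neighbors is 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .networks import BinaryNetwork, WeightedNetwork

__all__ = [
    "nodal_global_efficiency",
    "average_global_efficiency",
    "nodal_local_efficiency",
    "average_local_efficiency",
    "transitivity",
    "nodal_strength",
    "average_strength",
    "compute_all",
]


def _adj(A) -> np.ndarray:
    if isinstance(A, BinaryNetwork):
        return np.asarray(A.adjacency, dtype=float)
    M = np.asarray(A, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"adjacency must be square (got shape {M.shape})")
    return M


def _wmat(W) -> np.ndarray:
    if isinstance(W, WeightedNetwork):
        return W.weights
    return _adj(W)


def _inverse_distances(A: np.ndarray) -> np.ndarray:
    """Matrix of 1/d_ij on the binary graph, 0 for i=j and unreachable pairs.

    All-sources BFS by boolean matrix products — for the small dense graphs
    of atlas-based networks this beats sparse-graph shortest-path machinery
    by a wide margin inside the permutation loop.
    """
    adj = np.asarray(A) > 0
    n = adj.shape[0]
    adj8 = adj.astype(np.uint8)
    inv = np.zeros((n, n))
    reached = np.eye(n, dtype=bool)
    frontier = adj & ~reached
    d = 1
    while frontier.any():
        inv[frontier] = 1.0 / d
        reached |= frontier
        frontier = ((frontier.astype(np.uint8) @ adj8) > 0) & ~reached
        d += 1
    return inv


def nodal_global_efficiency(A, i: int | None = None):
    """Average inverse shortest-path length from each node to the rest.

    ``e_i = (1/(n-1)) * sum_{j != i} 1/d_ij`` with 1/inf = 0.  Returns the
    full vector, or a scalar when ``i`` is given.
    """
    M = _adj(A)
    n = M.shape[0]
    if n < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    e = _inverse_distances(M).sum(axis=1) / (n - 1)
    return float(e[i]) if i is not None else e


def average_global_efficiency(A) -> float:
    """Mean of the nodal global efficiencies."""
    return float(np.mean(nodal_global_efficiency(A)))


def nodal_local_efficiency(A, i: int | None = None):
    """Global efficiency of the subgraph induced by each node's neighbors
    (the node itself excluded); 0 for nodes with fewer than 2 neighbors."""
    M = _adj(A)
    n = M.shape[0]
    nodes = list(range(n)) if i is None else [i]
    out = np.zeros(len(nodes))
    for idx, u in enumerate(nodes):
        nb = np.flatnonzero(M[u] > 0)
        if nb.size < 2:
            out[idx] = 0.0
        else:
            out[idx] = average_global_efficiency(M[np.ix_(nb, nb)])
    return float(out[0]) if i is not None else out


def average_local_efficiency(A) -> float:
    return float(np.mean(nodal_local_efficiency(A)))


def transitivity(A) -> float:
    """Whole-network triangle closure: 3 * triangles / connected triples,
    i.e. trace(A^3) / sum_i k_i (k_i - 1); 0 when there are no triples."""
    M = _adj(A)
    k = M.sum(axis=1)
    denom = float(np.sum(k * (k - 1)))
    if denom == 0:
        return 0.0
    tri = float(np.trace(M @ M @ M))
    return tri / denom


def nodal_strength(W, i: int | None = None):
    """Sum of incident edge weights on the un-binarized weighted network."""
    M = _wmat(W)
    s = M.sum(axis=1)
    return float(s[i]) if i is not None else s


def average_strength(W) -> float:
    return float(np.mean(nodal_strength(W)))


def global_measures(A) -> dict[str, float]:
    """The three binary global measures of one network."""
    return {
        "global_efficiency": average_global_efficiency(A),
        "local_efficiency": average_local_efficiency(A),
        "transitivity": transitivity(A),
    }


def compute_all(
    sweep_nets: list[BinaryNetwork],
    W: WeightedNetwork,
    median_density: float | None = None,
) -> dict:
    """Measures for a full density sweep of one group network.

    Returns ``{"global": table per density, "strength": average strength
    (weighted, density-independent), "nodal": per-node table at the median
    density}``.
    """
    for net in sweep_nets:
        if net.labels != W.labels:
            raise ValidationError("sweep networks and W must share node labels")
    rows = []
    for net in sweep_nets:
        g = global_measures(net)
        g["density"] = net.density
        rows.append(g)
    glob = pd.DataFrame(rows)[
        ["density", "global_efficiency", "local_efficiency", "transitivity"]
    ]
    out = {"global": glob, "strength": average_strength(W), "nodal": None}
    if median_density is not None:
        match = [n for n in sweep_nets if n.density == median_density]
        if not match:
            raise ValidationError(
                f"median density {median_density} not among the sweep networks"
            )
        net = match[0]
        out["nodal"] = pd.DataFrame(
            {
                "node": list(W.labels),
                "global_efficiency": nodal_global_efficiency(net),
                "local_efficiency": nodal_local_efficiency(net),
                "strength": nodal_strength(W),
            }
        )
    return out
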