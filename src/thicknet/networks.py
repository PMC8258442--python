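"""Group covariance networks and density thresholding.

A group's network is the matrix of Pearson correlations of regional thickness
across the group's subjects.  Self-connections and negative correlations are
excluded (set to 0).  Binary networks are obtained by keeping the k largest
positive weights, with k = round(d/100 * n(n-1)/2) for density d; the sweep
runs 10-45% in 1% steps by default, bounded below by connectedness and above
by the onset of random-like topology (small-world index near 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError
from .io import CohortTable, NodeSet

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "DensitySweep",
    "correlation_network",
    "threshold_by_density",
    "sweep_networks",
    "qc_density_bounds",
]


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric nonnegative edge weights (retained Pearson r), zero diagonal."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if W.shape != (n, n):
            raise ValidationError(f"weight matrix {W.shape} does not match {n} labels")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(W < 0) or np.any(W > 1 + 1e-12):
            raise ValidationError("weights must lie in [0, 1] after exclusion")
        if np.any(np.diag(W) != 0):
            raise ValidationError("diagonal (self-connections) must be zero")
        object.__setattr__(self, "weights", W)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def max_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2


@dataclass(frozen=True)
class BinaryNetwork:
    """Adjacency obtained from a weighted network at one density (%)."""

    labels: tuple[str, ...]
    adjacency: np.ndarray
    density: float
    realized_density: float

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class DensitySweep:
    """Ordered densities (%) with the density at which nodal stats are read."""

    densities: tuple[float, ...] = tuple(float(d) for d in range(10, 46))
    median_density: float = 27.0

    def __post_init__(self):
        d = self.densities
        if len(d) == 0 or any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("densities must be strictly increasing")
        if self.median_density not in d:
            raise ValidationError(
                f"median density {self.median_density} not in the sweep"
            )


def correlation_network(
    cohort_subset: CohortTable, nodes: NodeSet
) -> WeightedNetwork:
    """Pearson-correlation network of one group.

    ``w_ij = max(0, r_ij)`` between the thickness of regions i and j across
    the subset's subjects; the diagonal is zero.
    """
    X = cohort_subset.thickness_matrix(nodes)
    if X.shape[0] < 3:
        raise ValidationError(
            f"need >= 3 subjects to estimate correlations (got {X.shape[0]})"
        )
    sd = X.std(axis=0)
    dead = [nodes.columns[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValidationError(f"zero thickness variance across subjects: {dead}")
    R = np.corrcoef(X, rowvar=False)
    W = np.clip(R, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)  # exact symmetry against fp asymmetry
    return WeightedNetwork(tuple(nodes.columns), W)


def _ranked_pairs(W: WeightedNetwork) -> list[tuple[int, int]]:
    """Positive-weight node pairs, heaviest first; ties broken by
    lexicographic (i, j) order for determinism."""
    n = W.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = W.weights[iu, ju]
    keep = w > 0
    pairs = sorted(
        zip(w[keep], iu[keep], ju[keep]), key=lambda t: (-t[0], t[1], t[2])
    )
    return [(int(i), int(j)) for _, i, j in pairs]


def _edge_count(d: float, n: int) -> int:
    # round-half-up, not banker's rounding, for cross-implementation clarity
    return int(np.floor(d / 100.0 * n * (n - 1) / 2 + 0.5))


def threshold_by_density(W: WeightedNetwork, d: float) -> BinaryNetwork:
    """Keep the k largest positive weights, k = round(d/100 * n(n-1)/2).

    If fewer than k positive weights exist, all of them are kept and a
    warning records the realized density.
    """
    if not (0 < d < 100):
        raise ParameterError(f"density must be in (0, 100) (got {d})")
    n = W.n_nodes
    k = _edge_count(d, n)
    pairs = _ranked_pairs(W)
    if len(pairs) < k:
        realized = 100.0 * len(pairs) / W.max_edges()
        warnings.warn(
            f"only {len(pairs)} positive weights available for requested "
            f"density {d}% (k={k}); realized density {realized:.1f}%",
            stacklevel=2,
        )
        k = len(pairs)
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in pairs[:k]:
        A[i, j] = A[j, i] = 1
    realized = 100.0 * k / W.max_edges() if W.max_edges() else 0.0
    return BinaryNetwork(W.labels, A, float(d), realized)


def sweep_networks(W: WeightedNetwork, sweep: DensitySweep) -> list[BinaryNetwork]:
    """One binary network per density; edge sets are nested across densities
    by construction (a single ranking of pairs, prefix-truncated)."""
    nets = []
    pairs = _ranked_pairs(W)
    n = W.n_nodes
    for d in sweep.densities:
        k = _edge_count(d, n)
        if len(pairs) < k:
            realized = 100.0 * len(pairs) / W.max_edges()
            warnings.warn(
                f"only {len(pairs)} positive weights for density {d}% "
                f"(realized {realized:.1f}%)",
                stacklevel=2,
            )
            k = len(pairs)
        A = np.zeros((n, n), dtype=np.int8)
        for i, j in pairs[:k]:
            A[i, j] = A[j, i] = 1
        realized = 100.0 * k / W.max_edges() if W.max_edges() else 0.0
        nets.append(BinaryNetwork(W.labels, A, float(d), realized))
    return nets


def _graph_stats(G: nx.Graph) -> tuple[float, float]:
    """(transitivity, mean shortest path over connected pairs)."""
    C = nx.transitivity(G)
    tot, cnt = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for v, d in dists.items():
            if d > 0:
                tot += d
                cnt += 1
    L = tot / cnt if cnt else np.nan
    return C, L


def qc_density_bounds(
    networks: list[BinaryNetwork],
    n_rand: int = 100,
    seed: int = 0,
    sigma_band: float = 0.1,
) -> pd.DataFrame:
    """Density-range quality control.

    For each binary network: connectedness, and the small-world index
    sigma = (C/C_rand)/(L/L_rand) against ``n_rand`` degree-preserving
    rewired graphs.  Densities that are disconnected, or whose sigma falls
    within ``sigma_band`` of 1 (random-like topology), are flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for net in networks:
        G = nx.from_numpy_array(net.adjacency)
        connected = nx.is_connected(G) if G.number_of_nodes() else False
        C, L = _graph_stats(G)
        cs, ls = [], []
        m = G.number_of_edges()
        for _ in range(n_rand):
            H = G.copy()
            if m >= 2:
                try:
                    nx.double_edge_swap(
                        H,
                        nswap=5 * m,
                        max_tries=500 * m,
                        seed=int(rng.integers(2**31)),
                    )
                except (nx.NetworkXError, nx.NetworkXAlgorithmError):
                    pass  # too few swappable edges; keep what was achieved
            c_r, l_r = _graph_stats(H)
            cs.append(c_r)
            ls.append(l_r)
        c_rand = float(np.nanmean(cs)) if cs else np.nan
        l_rand = float(np.nanmean(ls)) if ls else np.nan
        if c_rand and l_rand and C and L and np.isfinite([c_rand, l_rand, L]).all():
            sigma = (C / c_rand) / (L / l_rand)
        else:
            sigma = np.nan
        flags = []
        if not connected:
            flags.append("disconnected")
        if np.isfinite(sigma) and abs(sigma - 1.0) < sigma_band:
            flags.append("random-topology")
        rows.append(
            {
                "density": net.density,
                "connected": connected,
                "sigma": sigma,
                "flag": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
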