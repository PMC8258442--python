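"""Permutation-based group comparison of network measures.

Group networks are correlation-of-subjects objects, so the permutation null
relabels subjects and rebuilds both group networks from scratch on every
draw (correlation -> exclusion of negatives -> density thresholding ->
measures).  The two-tailed p-value uses the add-one estimator
``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)`` so p is never 0, and the
critical value reported as the 95% interval of the null is the m-th largest
|null| with ``m = floor(alpha * (n_perm + 1))`` — exactly the value for which
``|obs| > c`` and ``p <= alpha`` agree on every output.

Nodal comparisons at the median density are adjusted for multiplicity with
Benjamini-Hochberg FDR within each measure family; Hochberg's step-up method
is provided for post hoc p-vectors.
"""

from __future__ import annotations

import warnings
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ValidationError
from .io import CohortTable, NodeSet
from .measures import (
    average_global_efficiency,
    average_local_efficiency,
    nodal_global_efficiency,
    nodal_local_efficiency,
    transitivity,
)
from .networks import DensitySweep

__all__ = [
    "permute_groups",
    "compare_global",
    "compare_nodal",
    "fdr_adjust",
    "hochberg_adjust",
]

GLOBAL_MEASURES = ("global_efficiency", "local_efficiency", "transitivity")


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def permute_groups(
    subjects_a: Sequence[str],
    subjects_b: Sequence[str],
    seed: int = 0,
    n_perm: int = 1000,
) -> Iterator[tuple[list[str], list[str]]]:
    """Stream of relabeled (A*, B*) splits of the pooled subjects.

    Each draw reassigns the pool uniformly at random into groups of the
    original sizes; the stream is reproducible from the seed.
    """
    a, b = list(subjects_a), list(subjects_b)
    if set(a) & set(b):
        raise ParameterError("groups must be disjoint")
    pool = np.array(a + b)
    if pool.size < 4:
        raise ParameterError(f"pooled size must be >= 4 (got {pool.size})")
    na = len(a)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(pool.size)
        yield pool[perm[:na]].tolist(), pool[perm[na:]].tolist()


def _critical_value(abs_null: np.ndarray, alpha: float) -> float:
    """m-th largest |null| with m = floor(alpha*(n+1)); +inf when m = 0
    (n_perm too small for any rejection)."""
    m = int(np.floor(alpha * (abs_null.size + 1)))
    if m < 1:
        return np.inf
    return float(np.sort(abs_null)[::-1][m - 1])


def _p_two_tailed(abs_null: np.ndarray, abs_obs: float) -> float:
    return (1.0 + float(np.sum(abs_null >= abs_obs))) / (abs_null.size + 1.0)


def _resolve_groups(cohort: CohortTable, groups, group_col: str):
    """Accept (label_a, label_b) against a group column, or explicit id lists."""
    a, b = groups
    if isinstance(a, str) and isinstance(b, str):
        if group_col not in cohort.data.columns:
            raise ValidationError(
                f"cohort has no {group_col!r} column to resolve labels against"
            )
        col = cohort.data[group_col]
        for lab in (a, b):
            if not (col == lab).any():
                raise ValidationError(f"no subjects with group label {lab!r}")
        ids_a = cohort.data.index[col == a].tolist()
        ids_b = cohort.data.index[col == b].tolist()
        return ids_a, ids_b
    return list(a), list(b)


def _pooled_indices(cohort: CohortTable, ids_a, ids_b):
    """Positional row indices for the two groups and a canonical pooled order.

    The pooled order sorts the (multiset of) subject ids and the null always
    assigns the first ``min(n_a, n_b)`` permuted positions to the smaller
    group, so the stream of unordered relabeled splits — hence every
    two-tailed p-value — is invariant to swapping the group labels.
    """
    pos = {s: i for i, s in enumerate(cohort.subjects)}
    missing = [s for s in list(ids_a) + list(ids_b) if s not in pos]
    if missing:
        raise ValidationError(f"unknown subject ids: {sorted(set(missing))}")
    idx_a = np.array([pos[s] for s in ids_a], dtype=int)
    idx_b = np.array([pos[s] for s in ids_b], dtype=int)
    pool = np.sort(np.concatenate([idx_a, idx_b]))
    n_small = min(idx_a.size, idx_b.size)
    return idx_a, idx_b, pool, n_small


def _group_stats_global(
    X: np.ndarray, labels: tuple[str, ...], densities, k_list
) -> np.ndarray:
    """Measure vector for one group: (3 binary measures per density) + strength.

    X is the subjects-by-regions thickness block of that group.  Thresholding
    reuses a single weight ranking (prefix-nested), mirroring sweep_networks.
    """
    R = np.corrcoef(X, rowvar=False)
    W = np.clip(R, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))
    pos = w[order] > 0
    oi, oj = iu[order][pos], ju[order][pos]
    out = np.empty(3 * len(densities) + 1)
    A = np.zeros((n, n))
    prev = 0
    for di, k in enumerate(k_list):
        k = min(k, oi.size)
        if k > prev:
            A[oi[prev:k], oj[prev:k]] = 1
            A[oj[prev:k], oi[prev:k]] = 1
            prev = k
        out[3 * di] = average_global_efficiency(A)
        out[3 * di + 1] = average_local_efficiency(A)
        out[3 * di + 2] = transitivity(A)
    out[-1] = float(W.sum(axis=1).mean())
    return out


def compare_global(
    cohort: CohortTable,
    groups,
    nodes: NodeSet,
    sweep: DensitySweep | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Permutation comparison of global measures across the density sweep.

    Observed difference is measure(network(A)) - measure(network(B)),
    recomputed per density; efficiency/transitivity run on binary networks,
    strength once on the weighted networks.  Returns one row per (measure,
    density) with observed difference, the symmetric null critical interval,
    p-value and significance flag.
    """
    if sweep is None:
        sweep = DensitySweep()
    ids_a, ids_b = _resolve_groups(cohort, groups, group_col)
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValidationError("both groups need >= 3 subjects")
    idx_a, idx_b, pool, n_small = _pooled_indices(cohort, ids_a, ids_b)
    X = cohort.thickness_matrix(nodes)
    nn = len(nodes)
    max_e = nn * (nn - 1) // 2
    k_list = [int(np.floor(d / 100.0 * max_e + 0.5)) for d in sweep.densities]
    labels = tuple(nodes.columns)

    def stats(idx: np.ndarray) -> np.ndarray:
        return _group_stats_global(X[idx], labels, sweep.densities, k_list)

    obs = stats(idx_a) - stats(idx_b)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for p in range(n_perm):
        perm = pool[rng.permutation(pool.size)]
        null[p] = stats(perm[:n_small]) - stats(perm[n_small:])

    rows = []
    abs_null = np.abs(null)
    names = []
    for d in sweep.densities:
        for meas in GLOBAL_MEASURES:
            names.append((meas, d))
    names.append(("strength", np.nan))
    for j, (meas, d) in enumerate(names):
        crit = _critical_value(abs_null[:, j], alpha)
        p_val = _p_two_tailed(abs_null[:, j], abs(obs[j]))
        sig = abs(obs[j]) > crit
        # the CI rule and the p-rule must agree by construction
        assert sig == (p_val <= alpha)
        rows.append(
            {
                "measure": meas,
                "density": d,
                "observed": obs[j],
                "ci_low": -crit,
                "ci_high": crit,
                "p": p_val,
                "significant": sig,
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)


def _group_stats_nodal(X: np.ndarray, k: int) -> np.ndarray:
    """Nodal (e_glob, e_loc at one density; strength weighted) for one group."""
    R = np.corrcoef(X, rowvar=False)
    W = np.clip(R, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    order = np.lexsort((ju, iu, -w))
    pos = w[order] > 0
    oi, oj = iu[order][pos], ju[order][pos]
    kk = min(k, oi.size)
    A = np.zeros((n, n))
    A[oi[:kk], oj[:kk]] = 1
    A[oj[:kk], oi[:kk]] = 1
    return np.concatenate(
        [
            nodal_global_efficiency(A),
            nodal_local_efficiency(A),
            W.sum(axis=1),
        ]
    )


def compare_nodal(
    cohort: CohortTable,
    groups,
    nodes: NodeSet,
    density: float = 27.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Nodal permutation comparison at one density with FDR per measure family.

    Returns a row per (node, measure) with observed difference, raw
    permutation p and Benjamini-Hochberg adjusted p across nodes within the
    measure family.
    """
    ids_a, ids_b = _resolve_groups(cohort, groups, group_col)
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValidationError("both groups need >= 3 subjects")
    if 1.0 / (n_perm + 1.0) > alpha:
        warnings.warn(
            f"n_perm={n_perm} gives a minimum attainable p of "
            f"{1.0 / (n_perm + 1):.3g} > alpha={alpha}; no test can reach "
            "significance",
            stacklevel=2,
        )
    idx_a, idx_b, pool, n_small = _pooled_indices(cohort, ids_a, ids_b)
    X = cohort.thickness_matrix(nodes)
    nn = len(nodes)
    k = int(np.floor(density / 100.0 * nn * (nn - 1) / 2 + 0.5))

    obs = _group_stats_nodal(X[idx_a], k) - _group_stats_nodal(X[idx_b], k)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for p in range(n_perm):
        perm = pool[rng.permutation(pool.size)]
        null[p] = _group_stats_nodal(X[perm[:n_small]], k) - _group_stats_nodal(
            X[perm[n_small:]], k
        )
    abs_null = np.abs(null)

    measures = ["global_efficiency", "local_efficiency", "strength"]
    rows = []
    for mi, meas in enumerate(measures):
        cols = slice(mi * nn, (mi + 1) * nn)
        raw = np.array(
            [
                _p_two_tailed(abs_null[:, j], abs(obs[j]))
                for j in range(cols.start, cols.stop)
            ]
        )
        adj = fdr_adjust(list(raw))
        for ni, node in enumerate(nodes.columns):
            rows.append(
                {
                    "node": node,
                    "measure": meas,
                    "density": density,
                    "observed": obs[mi * nn + ni],
                    "p": raw[ni],
                    "p_fdr": adj[ni],
                    "significant": adj[ni] <= alpha,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiplicity adjustments
# ---------------------------------------------------------------------------

def _check_p(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        raise ValidationError("empty p-value list")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return arr


def fdr_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    arr = _check_p(p)
    return multipletests(arr, method="fdr_bh")[1].tolist()


def hochberg_adjust(p: Sequence[float]) -> list[float]:
    """Hochberg step-up adjusted p-values (original order kept)."""
    arr = _check_p(p)
    return multipletests(arr, method="simes-hochberg")[1].tolist()
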