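"""Synthetic cohorts with planted covariance structure.

The generator emulates the statistical shape of a cortical-thickness cohort:
ages drawn uniformly on a range, a linear age-related thinning shared by all
regions, and region-to-region correlated Gaussian noise with block (modular)
structure — segregated groups get several high-correlation blocks, merged
groups a single uniform block.  Cognitive scores are produced by a linear
model on a latent ability and age, so median splits on age and on a score
yield four non-trivial age x performance groups.

Nothing here models raw image acquisition, surface reconstruction or
test-retest measurement error; see the methods note for what the generator
does and does not emulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import CohortTable, NodeSet

__all__ = [
    "ScoreModel",
    "SyntheticSpec",
    "build_block_covariance",
    "plant_strength_elevation",
    "generate_cohort",
    "make_two_group_scenario",
]


@dataclass(frozen=True)
class ScoreModel:
    """Linear model linking a latent ability and age to one cognitive score:

    ``score = intercept + ability_weight * latent - age_weight * (age - age_ref)
    + Normal(0, noise_sd)``
    """

    intercept: float
    ability_weight: float
    age_weight: float
    noise_sd: float


#: default score models, loosely calibrated to typical neuropsychological
#: score scales (phonemic fluency ~ 20-50 words, naming ~ 20-30, etc.)
DEFAULT_SCORES: dict[str, ScoreModel] = {
    "pf": ScoreModel(35.0, 9.0, 0.25, 3.0),
    "bnt": ScoreModel(26.0, 2.0, 0.05, 1.5),
    "jlot": ScoreModel(13.0, 1.0, 0.03, 1.0),
    "vrt": ScoreModel(78.0, 8.0, 0.40, 6.0),
    "stroop": ScoreModel(37.0, 5.0, 0.25, 4.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic group.

    ``blocks`` partitions the node-set regions into latent modules;
    within-block pairs correlate at ``r_in``, between-block pairs at
    ``r_out``.  ``correlation`` (a full matrix) overrides the block recipe
    when planted structure beyond blocks is needed.
    """

    n_subjects: int
    regions: NodeSet
    blocks: tuple[tuple[str, ...], ...] = ()
    r_in: float = 0.6
    r_out: float = 0.0
    age_range: tuple[float, float] = (32.0, 79.0)
    atrophy_slope: float = 0.005  # mm per year, typical cortical thinning
    baseline_thickness: float = 2.5  # mm at the youngest age
    noise_sd: float = 0.12  # mm, between-subject thickness SD
    scores: dict = field(default_factory=lambda: dict(DEFAULT_SCORES))
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1 (got {self.n_subjects})")
        if not self.age_range[0] < self.age_range[1]:
            raise ParameterError(f"invalid age range {self.age_range}")
        if self.correlation is None:
            if not (-1 < self.r_out <= self.r_in < 1):
                raise ParameterError(
                    f"need -1 < r_out <= r_in < 1 (got r_in={self.r_in}, "
                    f"r_out={self.r_out})"
                )
        cols = set(self.regions.columns)
        blocked = [c for b in self.blocks for c in b]
        if self.blocks:
            if sorted(blocked) != sorted(cols):
                raise ParameterError(
                    "blocks must partition exactly the node-set regions"
                )
        if self.n_subjects < 2 * len(self.regions):
            warnings.warn(
                f"n_subjects={self.n_subjects} is below the recommended "
                f"2 x n_regions={2 * len(self.regions)}; correlation estimates "
                "will be noisy",
                stacklevel=2,
            )

    def block_index(self) -> np.ndarray:
        """Module index per region column (one block when none are given)."""
        cols = self.regions.columns
        if not self.blocks:
            return np.zeros(len(cols), dtype=int)
        idx = np.empty(len(cols), dtype=int)
        for b, members in enumerate(self.blocks):
            for m in members:
                idx[cols.index(m)] = b
        return idx


def build_block_covariance(
    blocks: Sequence[int] | np.ndarray,
    r_in: float,
    r_out: float,
    min_eig: float = 1e-8,
) -> np.ndarray:
    """Correlation matrix with ``r_in`` within blocks and ``r_out`` between.

    ``blocks`` is a module index per variable (e.g. ``[0, 0, 1]``).  If the
    target matrix is not positive definite it is shrunk toward the identity by
    the minimal convex weight that restores ``min_eig``, with a warning
    recording the weight.
    """
    if not (-1 < r_out <= r_in < 1):
        raise ParameterError(
            f"need -1 < r_out <= r_in < 1 (got r_in={r_in}, r_out={r_out})"
        )
    idx = np.asarray(blocks, dtype=int)
    same = idx[:, None] == idx[None, :]
    C = np.where(same, r_in, r_out).astype(float)
    np.fill_diagonal(C, 1.0)
    lo = np.linalg.eigvalsh(C)[0]
    if lo < min_eig:
        lam = (min_eig - lo) / (1.0 - lo)
        warnings.warn(
            f"block correlation matrix not positive definite (min eigenvalue "
            f"{lo:.3g}); shrunk toward identity with weight {lam:.3g}",
            stacklevel=2,
        )
        C = (1.0 - lam) * C + lam * np.eye(len(idx))
    return C


def plant_strength_elevation(
    corr: np.ndarray, nodes: Sequence[int], delta: float
) -> np.ndarray:
    """Raise the correlations of the designated ``nodes`` with all others by
    ``delta`` while lowering the remaining pairs so that, in expectation, only
    the designated nodes gain strength.

    With ``p`` designated and ``q`` other nodes, each other node gains
    ``p * delta`` from its edges to the designated nodes; spreading a
    compensating reduction of ``p * delta / (q - 1)`` over its ``q - 1``
    remaining pairs cancels that gain, confining the planted elevation to the
    designated nodes.
    """
    C = np.array(corr, dtype=float, copy=True)
    n = C.shape[0]
    des = np.zeros(n, dtype=bool)
    des[list(nodes)] = True
    q = int((~des).sum())
    if q < 2:
        raise ParameterError("need at least 2 non-designated nodes")
    comp = len(list(nodes)) * delta / (q - 1)
    cross = des[:, None] ^ des[None, :]
    both_des = des[:, None] & des[None, :]
    neither = ~des[:, None] & ~des[None, :]
    C[cross] += delta
    C[both_des] += delta
    C[neither] -= comp
    np.fill_diagonal(C, 1.0)
    off = C[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ParameterError("delta pushes a correlation outside (-1, 1)")
    lo = np.linalg.eigvalsh(C)[0]
    if lo < 1e-8:
        lam = (1e-8 - lo) / (1.0 - lo)
        warnings.warn(
            f"planted matrix repaired toward identity with weight {lam:.3g}",
            stacklevel=2,
        )
        C = (1.0 - lam) * C + lam * np.eye(n)
    return C


def make_strength_localization_scenario(
    regions: NodeSet,
    designated: Sequence[int],
    n_per_group: int = 400,
    base_r: float = 0.5,
    delta: float = 0.18,
    seed: int = 0,
    labels: tuple[str, str] = ("elevated", "reference"),
) -> CohortTable:
    """Two-group cohort where only the designated nodes gain strength.

    The elevated group's correlation matrix boosts the designated nodes'
    correlations by ``delta`` (repaired to positive definite if needed); the
    reference group is uniform with its correlation chosen so non-designated
    nodes have exactly the same expected strength in both groups.  Nodal
    strength comparisons should therefore flag the designated nodes and no
    others.
    """
    n = len(regions)
    base = np.full((n, n), base_r)
    np.fill_diagonal(base, 1.0)
    C_elev = plant_strength_elevation(base, designated, delta)
    other = next(i for i in range(n) if i not in set(designated))
    s_other = C_elev[other].sum() - 1.0
    r_ref = s_other / (n - 1)
    C_ref = np.full((n, n), r_ref)
    np.fill_diagonal(C_ref, 1.0)
    spec_elev = SyntheticSpec(
        n_subjects=n_per_group, regions=regions, correlation=C_elev,
        atrophy_slope=0.0, seed=seed,
    )
    spec_ref = SyntheticSpec(
        n_subjects=n_per_group, regions=regions, correlation=C_ref,
        atrophy_slope=0.0, seed=seed,
    )
    return make_two_group_scenario(spec_elev, spec_ref, labels=labels)


def _spec_correlation(spec: SyntheticSpec) -> np.ndarray:
    if spec.correlation is not None:
        C = np.asarray(spec.correlation, dtype=float)
        if C.shape != (len(spec.regions), len(spec.regions)):
            raise ParameterError(
                f"correlation matrix shape {C.shape} does not match the "
                f"{len(spec.regions)} node-set regions"
            )
        return C
    return build_block_covariance(spec.block_index(), spec.r_in, spec.r_out)


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> CohortTable:
    """Draw one synthetic cohort, fully reproducible from the seed.

    Thickness of region j for subject i:
    ``baseline - atrophy_slope * (age_i - age_min) + noise_sd * e_ij``
    with ``e_i ~ Normal(0, C)`` and C the block correlation matrix.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, k = spec.n_subjects, len(spec.regions)
    C = _spec_correlation(spec)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(k))

    age = rng.uniform(*spec.age_range, size=n)
    noise = rng.standard_normal((n, k)) @ L.T
    thick = (
        spec.baseline_thickness
        - spec.atrophy_slope * (age - spec.age_range[0])[:, None]
        + spec.noise_sd * noise
    )
    thick = np.clip(thick, 0.05, None)  # thickness must stay physical (>0)

    latent = rng.standard_normal(n)
    age_ref = 0.5 * (spec.age_range[0] + spec.age_range[1])
    df = pd.DataFrame(index=pd.Index([f"s{i:04d}" for i in range(n)], name="subject"))
    df["age"] = age
    df["sex"] = rng.choice(["F", "M"], size=n)
    for name, m in spec.scores.items():
        df[name] = (
            m.intercept
            + m.ability_weight * latent
            - m.age_weight * (age - age_ref)
            + m.noise_sd * rng.standard_normal(n)
        )
    for j, col in enumerate(spec.regions.columns):
        df[col] = thick[:, j]
    return CohortTable(df)


def make_two_group_scenario(
    spec_hp: SyntheticSpec,
    spec_lp: SyntheticSpec,
    labels: tuple[str, str] = ("HP", "LP"),
) -> CohortTable:
    """Concatenate two groups drawn under different covariance structures.

    The canonical use plants a segregated (2-block) structure for the
    high-performance group and a merged single block for the low-performance
    group; subjects carry a ``group`` column.
    """
    if spec_hp.regions.columns != spec_lp.regions.columns:
        raise ParameterError("the two specs must share the same region set")
    ss = np.random.SeedSequence(spec_hp.seed)
    s_hp, s_lp = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    hp = generate_cohort(spec_hp, seed=s_hp).data
    lp = generate_cohort(spec_lp, seed=s_lp).data
    hp = hp.set_index(("hp_" + hp.index.astype(str)).rename("subject"))
    lp = lp.set_index(("lp_" + lp.index.astype(str)).rename("subject"))
    hp.insert(0, "group", labels[0])
    lp.insert(0, "group", labels[1])
    return CohortTable(pd.concat([hp, lp]))
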