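"""Median-split stratification into age x performance groups.

The cohort is split at the median of age and of a selected cognitive score
(or a z-composite of several scores), crossing the two splits into the four
groups YA-LP, YA-HP, OA-LP, OA-HP (younger/older age x low/high performance).

Tie rule: a value equal to the median goes to the *low* group.  The rule is
arbitrary but deterministic, and is recorded with the thresholds so runs are
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import CohortTable

GROUP_LABELS = ("YA-LP", "YA-HP", "OA-LP", "OA-HP")


def composite_score(
    scores: pd.DataFrame, components: list[str] | tuple[str, ...]
) -> pd.Series:
    """Equal-weight mean of z-scored components (sample SD, n-1 denominator).

    Raises if a component is missing, has missing values, or has zero
    variance (z-score undefined).
    """
    missing = [c for c in components if c not in scores.columns]
    if missing:
        raise ValidationError(f"missing composite components: {missing}")
    if len(components) == 0:
        raise ValidationError("composite requires at least one component")
    zs = []
    for c in components:
        v = scores[c].astype(float)
        if v.isna().any():
            bad = scores.index[v.isna()].tolist()
            raise ValidationError(f"component {c!r} missing for subjects {bad}")
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"component {c!r} has zero variance")
        zs.append((v - v.mean()) / sd)
    return sum(zs) / len(components)


def median_split(values: pd.Series) -> tuple[pd.Series, float]:
    """Split at the sample median: ``low`` if value <= median, else ``high``.

    Returns the labels and the threshold.  The median is the midpoint of the
    two central order statistics for even n.
    """
    v = values.astype(float)
    if len(v) < 2:
        raise ValidationError("median split requires at least 2 subjects")
    if v.isna().any() or not np.isfinite(v).all():
        bad = values.index[~np.isfinite(v)].tolist()
        raise ValidationError(f"non-finite values for subjects {bad}")
    if v.nunique() == 1:
        raise ValidationError(
            f"all values identical ({v.iloc[0]}); median split is degenerate"
        )
    thr = float(v.median())
    labels = pd.Series(np.where(v <= thr, "low", "high"), index=v.index)
    return labels, thr


@dataclass
class GroupAssignment:
    """Result of the 2x2 stratification."""

    assignments: pd.Series  # subject -> group label
    age_threshold: float
    perf_threshold: float
    age_var: str
    perf_var: str

    @property
    def sizes(self) -> dict[str, int]:
        counts = self.assignments.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}

    def subjects(self, label: str) -> list[str]:
        if label not in GROUP_LABELS:
            raise ValidationError(
                f"unknown group label {label!r}; expected one of {GROUP_LABELS}"
            )
        return self.assignments.index[self.assignments == label].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.assignments.index, "group": self.assignments.values}
        )


def stratify(
    cohort: CohortTable, age_var: str = "age", perf_var: str = "pf"
) -> GroupAssignment:
    """Cross the median splits on age and performance into four groups."""
    df = cohort.data
    for var in (age_var, perf_var):
        if var not in df.columns:
            raise ValidationError(f"stratification variable {var!r} not in cohort")
    age_lab, age_thr = median_split(df[age_var])
    perf_lab, perf_thr = median_split(df[perf_var])
    age_part = np.where(age_lab == "low", "YA", "OA")
    perf_part = np.where(perf_lab == "low", "LP", "HP")
    groups = pd.Series(
        [f"{a}-{p}" for a, p in zip(age_part, perf_part)], index=df.index
    )
    assignment = GroupAssignment(groups, age_thr, perf_thr, age_var, perf_var)
    empty = [g for g, n in assignment.sizes.items() if n == 0]
    if empty:
        warnings.warn(f"empty stratification groups: {empty}", stacklevel=2)
    return assignment
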