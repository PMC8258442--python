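"""Input/output: thickness tables, node sets, pipeline configuration, results.

The tabular input convention is the subjects-by-regions export of standard
surface-reconstruction toolchains (one subject per row; one column per atlas
region, named ``{lh,rh}_<label>``), carried in a :class:`CohortTable` together
with per-subject covariates.  Region labels are matched exactly — silent
mis-mapping of cortical regions is worse than a hard error, so no fuzzy
matching is attempted.

Floating-point output is printed with 6 significant digits; full precision is
kept internally.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ParseError, ValidationError

_REGION_RE = re.compile(r"^(lh|rh)_[A-Za-z0-9]+$")
_HEMI = {"lh": "left", "rh": "right"}
_HEMI_INV = {"left": "lh", "right": "rh"}

#: columns that are never treated as cognitive scores
_NON_SCORE = {"subject", "age", "sex", "group"}


def _fmt(x) -> str:
    """Format one value with 6 significant digits (non-floats unchanged)."""
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


@dataclass(frozen=True)
class NodeSet:
    """A named, ordered list of atlas regions defining one network's nodes."""

    name: str
    regions: tuple[tuple[str, str], ...]  # (hemisphere, label)

    def __post_init__(self):
        problems = []
        if len(self.regions) < 3:
            problems.append(f"node set {self.name!r} has fewer than 3 regions")
        cols = [f"{_HEMI_INV.get(h, '?')}_{lab}" for h, lab in self.regions]
        if len(set(cols)) != len(cols):
            problems.append(f"node set {self.name!r} has duplicate region labels")
        for h, lab in self.regions:
            if h not in _HEMI_INV:
                problems.append(
                    f"node set {self.name!r}: hemisphere {h!r} not in {{left, right}}"
                )
        if problems:
            raise ValidationError("; ".join(problems))

    @classmethod
    def from_columns(cls, name: str, columns: Iterable[str]) -> "NodeSet":
        """Build from ``lh_*``/``rh_*`` column names."""
        regions = []
        for c in columns:
            m = _REGION_RE.match(c)
            if m is None:
                raise ValidationError(
                    f"region column {c!r} does not match the "
                    "'{lh,rh}_<label>' naming convention"
                )
            hemi, label = c.split("_", 1)
            regions.append((_HEMI[hemi], label))
        return cls(name=name, regions=tuple(regions))

    @property
    def columns(self) -> list[str]:
        """Region labels in table-column form (``lh_<label>``)."""
        return [f"{_HEMI_INV[h]}_{lab}" for h, lab in self.regions]

    def __len__(self) -> int:
        return len(self.regions)


class CohortTable:
    """Per-subject covariates plus regional cortical-thickness values (mm).

    Wraps a :class:`pandas.DataFrame` indexed by unique subject id.  Columns
    matching ``{lh,rh}_<label>`` are thickness regions; ``age``/``sex``/
    ``group`` are demographics; every other numeric column is a cognitive
    score.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if df.index.name != "subject":
            if "subject" not in df.columns:
                raise FormatError("missing mandatory column 'subject'")
            df = df.set_index("subject")
        df.index = df.index.astype(str)
        problems = []
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            problems.append(f"duplicate subject ids: {dups}")
        if "age" not in df.columns:
            problems.append("missing mandatory column 'age'")
        else:
            age = pd.to_numeric(df["age"], errors="coerce")
            bad = df.index[~np.isfinite(age) | (age <= 0)].tolist()
            if bad:
                problems.append(f"non-finite or non-positive age for subjects {bad}")
            df["age"] = age
        region_cols = [c for c in df.columns if _REGION_RE.match(c)]
        for c in region_cols:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[~np.isfinite(vals) | (vals <= 0)].tolist()
            if bad:
                problems.append(
                    f"thickness column {c!r} non-finite or non-positive "
                    f"for subjects {bad}"
                )
            df[c] = vals
        if problems:
            raise ValidationError("; ".join(problems))
        self.data = df
        self.region_columns = region_cols

    # -- accessors ---------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def score_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in _NON_SCORE and c not in self.region_columns
        ]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def thickness_matrix(self, nodes: NodeSet) -> np.ndarray:
        """Subjects x regions thickness matrix for one node set."""
        missing = [c for c in nodes.columns if c not in self.data.columns]
        if missing:
            raise ValidationError(
                f"node set {nodes.name!r} references regions absent from the "
                f"cohort table: {missing}"
            )
        return self.data[nodes.columns].to_numpy(dtype=float)

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        ids = list(subject_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown subject ids: {missing}")
        return CohortTable(self.data.loc[ids])

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.data.equals(other.data)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PipelineConfig:
    """Validated configuration of a full analysis run.

    Defaults follow the standard design of thickness-covariance studies:
    densities swept from 10% to 45% in 1% steps, nodal statistics evaluated at
    the median density 27%, 1000 permutations, alpha 0.05.
    """

    node_sets: dict[str, NodeSet] = field(default_factory=dict)
    density_min: float = 10.0
    density_max: float = 45.0
    density_step: float = 1.0
    median_density: float = 27.0
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    gamma: float = 1.0
    n_restarts: int = 100
    age_var: str = "age"
    perf_var: str = "pf"
    composite_components: tuple[str, ...] = ()
    contrasts: tuple[tuple[str, str], ...] = (
        ("YA-LP", "YA-HP"),
        ("OA-LP", "YA-LP"),
        ("OA-HP", "YA-HP"),
        ("OA-LP", "OA-HP"),
    )
    landmarks: tuple[str, ...] = ()
    cohort_path: str | None = None

    def __post_init__(self):
        problems = []
        if not (0 < self.density_min < self.density_max < 100):
            problems.append(
                "density range must satisfy 0 < min < max < 100 "
                f"(got min={self.density_min}, max={self.density_max})"
            )
        if self.density_step <= 0:
            problems.append(f"density step must be > 0 (got {self.density_step})")
        if not (self.density_min <= self.median_density <= self.density_max):
            problems.append(
                f"median density {self.median_density} outside "
                f"[{self.density_min}, {self.density_max}]"
            )
        if self.n_perm < 1:
            problems.append(f"n_perm must be >= 1 (got {self.n_perm})")
        if not (0 < self.alpha < 1):
            problems.append(f"alpha must be in (0, 1) (got {self.alpha})")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def densities(self) -> tuple[float, ...]:
        n = int(round((self.density_max - self.density_min) / self.density_step))
        return tuple(self.density_min + i * self.density_step for i in range(n + 1))

    def to_dict(self) -> dict:
        d = {
            "node_sets": {k: v.columns for k, v in self.node_sets.items()},
            "density": {
                "min": self.density_min,
                "max": self.density_max,
                "step": self.density_step,
            },
            "median_density": self.median_density,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "seed": self.seed,
            "gamma": self.gamma,
            "n_restarts": self.n_restarts,
            "stratification": {"age_var": self.age_var, "perf_var": self.perf_var},
            "composite_components": list(self.composite_components),
            "contrasts": [list(c) for c in self.contrasts],
            "landmarks": list(self.landmarks),
        }
        if self.cohort_path is not None:
            d["cohort"] = self.cohort_path
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in {"csv", "tsv"}:
            raise FormatError(f"unknown table dialect {dialect!r} (use 'csv' or 'tsv')")
        return "," if dialect == "csv" else "\t"
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_thickness_table(path, dialect: str | None = None) -> CohortTable:
    """Read a subjects-by-regions thickness table (TSV or CSV).

    The header must name ``subject``, ``age`` and the region columns in the
    exact ``{lh,rh}_<label>`` convention.  A non-numeric or missing thickness
    cell is a hard parse error naming the data row (1-based) and column — the
    analysis is complete-case and never imputes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"thickness table not found: {path}")
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    for col in ("subject", "age"):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    region_cols = [c for c in raw.columns if _REGION_RE.match(c)]
    out = raw.copy()
    for c in raw.columns:
        if c in ("subject", "sex", "group"):
            continue
        strict = c in region_cols or c == "age"
        vals = np.empty(len(raw))
        for i, cell in enumerate(raw[c].to_numpy()):
            try:
                # python float() round-trips repr output exactly, which
                # pandas' fast to_numeric parser does not guarantee
                v = float(cell)
            except (TypeError, ValueError):
                v = np.nan
                if strict:
                    raise ParseError(
                        f"non-numeric value {cell!r} at row {i + 1}, column {c}"
                    ) from None
            if strict and not np.isfinite(v):
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 1}, column {c}"
                )
            vals[i] = v
        out[c] = vals
    return CohortTable(out)


def write_cohort(cohort: CohortTable, path, sep: str = "\t") -> None:
    """Write a cohort table; numeric cells keep full repr precision so a
    write/read round trip reproduces values exactly."""
    df = cohort.data.reset_index()
    df.to_csv(path, sep=sep, index=False, float_format=lambda v: repr(float(v)))


def read_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration, applying documented defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise FormatError(f"config root must be a mapping (got {type(doc).__name__})")
    return config_from_dict(doc)


def config_from_dict(doc: Mapping) -> PipelineConfig:
    kwargs: dict = {}
    dens = doc.get("density", {}) or {}
    if "min" in dens:
        kwargs["density_min"] = float(dens["min"])
    if "max" in dens:
        kwargs["density_max"] = float(dens["max"])
    if "step" in dens:
        kwargs["density_step"] = float(dens["step"])
    for key in ("median_density", "alpha", "gamma"):
        if key in doc:
            kwargs[key] = float(doc[key])
    for key in ("n_perm", "seed", "n_restarts"):
        if key in doc:
            kwargs[key] = int(doc[key])
    strat = doc.get("stratification", {}) or {}
    if "age_var" in strat:
        kwargs["age_var"] = str(strat["age_var"])
    if "perf_var" in strat:
        kwargs["perf_var"] = str(strat["perf_var"])
    if "composite_components" in doc:
        kwargs["composite_components"] = tuple(doc["composite_components"])
    if "contrasts" in doc:
        kwargs["contrasts"] = tuple(tuple(c) for c in doc["contrasts"])
    if "landmarks" in doc:
        kwargs["landmarks"] = tuple(doc["landmarks"])
    if "cohort" in doc:
        kwargs["cohort_path"] = str(doc["cohort"])
    node_sets = {}
    for name, cols in (doc.get("node_sets", {}) or {}).items():
        node_sets[name] = NodeSet.from_columns(name, cols)
    if node_sets:
        kwargs["node_sets"] = node_sets
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """Everything a run produces: named tables and named weighted matrices."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    matrices: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    config: PipelineConfig | None = None
    seed: int | None = None


def _write_table(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def _write_matrix(labels: list[str], mat: np.ndarray, path: Path) -> None:
    df = pd.DataFrame(mat, index=labels, columns=labels)
    df = df.map(_fmt)
    df.to_csv(path, sep="\t", index_label="node")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(bundle: ResultBundle, out_dir, timestamp: bool = False) -> dict:
    """Write a result bundle as TSV tables plus a plain-text run manifest.

    Returns the manifest as a dict (also written to ``manifest.txt``).
    Timestamps are off by default so identical runs produce byte-identical
    output directories.
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    files: dict[str, str] = {}
    for name, df in bundle.tables.items():
        p = out_dir / f"{name}.tsv"
        _write_table(df, p)
        files[p.name] = _sha256(p)
    for name, (labels, mat) in bundle.matrices.items():
        p = out_dir / f"{name}.matrix.tsv"
        _write_matrix(labels, mat, p)
        files[p.name] = _sha256(p)

    manifest: dict = {
        "version": __version__,
        "seed": bundle.seed if bundle.seed is not None else (
            bundle.config.seed if bundle.config is not None else None
        ),
        "config_hash": bundle.config.config_hash() if bundle.config else None,
        "files": files,
    }
    if timestamp:
        import datetime

        manifest["timestamp"] = datetime.datetime.now().isoformat()

    lines = [f"version\t{manifest['version']}", f"seed\t{manifest['seed']}"]
    if manifest["config_hash"]:
        lines.append(f"config_hash\t{manifest['config_hash']}")
    if timestamp:
        lines.append(f"timestamp\t{manifest['timestamp']}")
    for fname in sorted(files):
        lines.append(f"file\t{fname}\t{files[fname]}")
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return manifest
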