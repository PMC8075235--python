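"""File I/O, run configuration and fixture generation.

Cohorts and factor tables travel as TSV (``id``, ``status``, factor
columns, optional ``group``); result tables as CSV.  Every file written
here is accompanied by a ``<file>.meta.json`` sidecar holding the
configuration and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scenarios as _s

__all__ = [
    "RunConfig",
    "load_config",
    "read_cohort",
    "write_cohort",
    "read_factor_table",
    "write_factor_table",
    "write_provenance",
    "read_provenance",
    "generate_fixture",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("null", "confounder1", "additive-o")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated parameters for a simulation/experiment run."""

    scenario: str = "and"
    prevalence: float = 0.005
    prevalence_grid: tuple[float, ...] = field(default=(0.005,))
    n_components: int | None = None
    threshold: int | None = None
    n_individuals: int = _s.DEFAULT_N_INDIVIDUALS
    n_replicates: int = 1000
    subsample: bool = True
    seed: int = 0
    min_cell: int = 5
    bootstrap_resamples: int = 1000
    group_prevalence_ratio: float = _s.DEFAULT_GROUP_PREVALENCE_RATIO

    def __post_init__(self) -> None:
        _s.Logic(self.scenario)  # raises on unknown scenario
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        for p in self.prevalence_grid:
            if not 0.0 < p < 1.0:
                raise ValueError(f"grid prevalence {p} outside (0,1)")
        if self.n_individuals <= 0 or self.n_replicates <= 0:
            raise ValueError("n_individuals and n_replicates must be positive")
        if self.min_cell < 0 or self.bootstrap_resamples < 1:
            raise ValueError("min_cell >= 0 and bootstrap_resamples >= 1 required")
        object.__setattr__(self, "prevalence_grid", tuple(self.prevalence_grid))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prevalence_grid"] = list(self.prevalence_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML or JSON (detected by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raise ValueError(f"config must be .yaml/.yml/.json, got {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# Provenance sidecars
# ---------------------------------------------------------------------------

def write_provenance(path: str | Path, payload: dict) -> Path:
    """Write ``<path>.meta.json`` describing how the file was produced."""
    meta_path = Path(str(path) + ".meta.json")
    meta_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return meta_path


def read_provenance(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".meta.json").read_text())


# ---------------------------------------------------------------------------
# Cohort / factor-table TSV
# ---------------------------------------------------------------------------

def _validate_binary(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    for col in columns:
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # 1-based plus header line
            raise ValueError(
                f"{path}:{line}: column {col!r} has non-binary value "
                f"{vals[bad][0]!r}"
            )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "status" not in df.columns:
        raise ValueError(f"{path}: missing required 'status' column")
    factor_cols = [c for c in df.columns if c not in ("id", "status", "group")]
    if df.empty:
        return df
    _validate_binary(df, ["status"] + factor_cols, path)
    return df


def read_cohort(path: str | Path) -> _s.Cohort:
    """Read a cohort TSV; raises with the offending line on bad values."""
    df = _read_table(path)
    return _s.Cohort(data=df.drop(columns=["id"], errors="ignore"))


def write_cohort(
    cohort: _s.Cohort, path: str | Path, provenance: dict | None = None
) -> Path:
    """Write a cohort TSV (id, status, factors, optional group)."""
    path = Path(path)
    df = cohort.data.copy()
    df.insert(0, "id", np.arange(len(df)))
    ordered = ["id", "status"] + cohort.factor_names
    if "group" in df.columns:
        ordered.append("group")
    df[ordered].to_csv(path, sep="\t", index=False)
    if provenance is not None:
        write_provenance(path, provenance)
    return path


def read_factor_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path)


def write_factor_table(
    table: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> Path:
    path = Path(path)
    df = table.copy()
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)
    if provenance is not None:
        write_provenance(path, provenance)
    return path


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def generate_fixture(
    kind: str,
    size: int,
    seed: int,
    *,
    n_loci: int = 50,
    case_fraction: float = 0.5,
    anchor: str = "anchor",
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic multi-locus factor table with known ground truth.

    Kinds
    -----
    ``"null"``
        Every locus independent of status (same frequency in cases and
        controls): no associations, AMLES mostly undefined.
    ``"confounder1"``
        Anchor and loci more frequent in cases than controls, independent
        within each status pool: every pair has exactly multiplicative
        expected odds ratios.
    ``"additive-o"``
        Shared 50/50 group split; the anchor carries risk only in one
        group and the test loci only in the other: every (anchor, locus)
        pair has exactly additive expected odds ratios.

    Returns the table and a metadata dict with per-locus frequencies and
    the expected pairwise pattern; writes TSV + sidecar when ``path``
    is given.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must be in (0,1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    n_cases = int(round(size * case_fraction))
    if n_cases == 0 or n_cases == size:
        raise ValueError("size too small for the case fraction")
    status = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(size - n_cases, dtype=np.int8)]
    )
    names = [anchor] + [f"L{i + 1:03d}" for i in range(n_loci)]
    freqs = {}
    for name in names:
        low, high, _ = _s.draw_factor_frequencies("X-like", rng)
        freqs[name] = (low, high)
    cols: dict[str, np.ndarray] = {"status": status}
    if kind == "null":
        for name in names:
            low, _ = freqs[name]
            cols[name] = (rng.random(size) < low).astype(np.int8)
        expected = "null (no association; AMLES unstable/undefined)"
    elif kind == "confounder1":
        for name in names:
            low, high = freqs[name]
            freq = np.where(status == 1, high, low)
            cols[name] = (rng.random(size) < freq).astype(np.int8)
        expected = "multiplicative (AMLES ~ 1 for every pair)"
    else:  # additive-o
        group = (rng.random(size) < 0.5).astype(np.int8)
        low_a, high_a = freqs[anchor]
        anchor_freq = np.where((group == 1) & (status == 1), high_a, low_a)
        cols[anchor] = (rng.random(size) < anchor_freq).astype(np.int8)
        for name in names[1:]:
            low, high = freqs[name]
            freq = np.where((group == 0) & (status == 1), high, low)
            cols[name] = (rng.random(size) < freq).astype(np.int8)
        cols["group"] = group
        expected = "additive (AMLES ~ 0 for every anchor-locus pair)"
    table = pd.DataFrame(cols)
    meta = {
        "kind": kind,
        "seed": seed,
        "size": size,
        "n_loci": n_loci,
        "case_fraction": case_fraction,
        "anchor": anchor,
        "expected_pattern": expected,
        "locus_frequencies": {k: list(v) for k, v in freqs.items()},
    }
    if path is not None:
        write_factor_table(table, path, provenance=meta)
    return table, meta
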