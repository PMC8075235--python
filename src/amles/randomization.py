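"""Null-generating randomizations and the anchor-vs-many pairwise scan.

A *factor table* is a DataFrame of individuals with a binary ``status``
column, one anchor risk factor and many binary test factors.  Two
randomizations turn an observed table into a synthetic null:

* ``rand1`` permutes every factor column independently within cases and
  within controls.  It preserves the per-status marginal count of every
  factor exactly while destroying any within-status dependence between
  factors — a positive control that forces multiplicative odds ratios (the
  data-reuse confounder structure).
* ``rand2`` splits individuals into two random halves and resamples the
  anchor from the control-stratum distribution in one half and each test
  factor from the control-stratum distribution in the other — an additive
  odds-ratio control mirroring the two-group additive scheme.

``pairwise_scan`` computes the full effect-estimate row (ORs, AMLES, RERI)
of every test factor against the anchor, with the minimum-cell validity
filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _m

__all__ = [
    "rand1_shuffle_within_status",
    "rand2_group_split_null",
    "pairwise_scan",
]

RESERVED_COLUMNS = ("id", "status", "group")


def _factor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def _check_table(table: pd.DataFrame, columns: list[str] | None = None) -> None:
    if "status" not in table.columns:
        raise ValueError("factor table needs a 'status' column")
    for c in ["status"] + (columns if columns is not None else _factor_columns(table)):
        if not np.isin(table[c].to_numpy(), (0, 1)).all():
            raise ValueError(f"column {c!r} contains non-binary values")


def rand1_shuffle_within_status(
    table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute each factor column independently within each status stratum.

    Per-status marginal counts of every factor are preserved exactly; the
    status column itself is untouched.
    """
    _check_table(table)
    out = table.copy()
    status = table["status"].to_numpy()
    for stratum in (0, 1):
        idx = np.flatnonzero(status == stratum)
        for col in _factor_columns(table):
            perm = rng.permutation(idx.size)
            out.iloc[idx, out.columns.get_loc(col)] = (
                table[col].to_numpy()[idx][perm]
            )
    return out


def rand2_group_split_null(
    table: pd.DataFrame, anchor: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Two-group resampling null (additive odds-ratio control).

    Individuals are split 50/50 at random.  In group 1 the anchor column is
    resampled, per individual independently and with replacement, from the
    control-stratum anchor values; in group 2 every test factor column is
    resampled likewise from its control-stratum values.  Status is never
    modified, so case/control counts are preserved.
    """
    if anchor not in table.columns:
        raise ValueError(f"anchor {anchor!r} not in table")
    _check_table(table)
    out = table.copy()
    status = table["status"].to_numpy()
    controls = np.flatnonzero(status == 0)
    if controls.size == 0:
        raise ValueError("table has no controls to resample from")
    n = len(table)
    in_group1 = rng.random(n) < 0.5
    test_factors = [c for c in _factor_columns(table) if c != anchor]

    def _resample(col: str, rows: np.ndarray) -> None:
        pool = table[col].to_numpy()[controls]
        draws = pool[rng.integers(0, pool.size, size=rows.size)]
        out.iloc[rows, out.columns.get_loc(col)] = draws

    _resample(anchor, np.flatnonzero(in_group1))
    rows2 = np.flatnonzero(~in_group1)
    for col in test_factors:
        _resample(col, rows2)
    return out


def pairwise_scan(
    table: pd.DataFrame,
    anchor: str,
    min_cell: int = _m.DEFAULT_MIN_CELL,
) -> pd.DataFrame:
    """Effect estimates of every test factor against the anchor.

    Returns one row per test factor with the OR-based estimate fields;
    rows that fail the minimum-cell filter, or whose AMLES is undefined,
    are kept and flagged so downstream counts stay auditable.
    """
    if anchor not in table.columns:
        raise ValueError(f"anchor {anchor!r} not in table")
    test_factors = [c for c in _factor_columns(table) if c != anchor]
    if not test_factors:
        raise ValueError("no test factors besides the anchor")
    _check_table(table, columns=[anchor] + test_factors)
    status = table["status"].to_numpy()
    a = table[anchor].to_numpy()
    rows = []
    for col in test_factors:
        z = table[col].to_numpy()
        code = ((a * 2 + z) * 2 + status).astype(np.int64)
        counts = np.bincount(code, minlength=8).reshape(2, 2, 2).astype(float)
        ct = _m.ContingencyTable(counts=counts, factor_names=(anchor, col))
        est = _m.odds_ratios(ct, min_cell=min_cell)
        row = {"factor": col, "anchor": anchor}
        row.update(est.as_dict())
        row["amles_defined"] = bool(np.isfinite(est.amles))
        rows.append(row)
    return pd.DataFrame(rows)
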