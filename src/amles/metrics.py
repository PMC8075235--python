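"""Effect-scale metrics for pairs (and triples) of dichotomous risk factors.

The central quantity is AMLES, the additive-to-multiplicative linear effect
scale.  With OR00 = 1 as reference,

    expected(additive)       = OR10 + OR01 - 1
    expected(multiplicative) = OR10 * OR01
    AMLES = (OR11 - expected(additive)) / (expected(mult) - expected(additive))

so AMLES = 0 means the joint effect is exactly additive, 1 exactly
multiplicative, and intermediate values map onto multifactorial-threshold
scenarios through the threshold fraction f_thr = (t-1)/(F-1) via
median AMLES ~ sqrt(f_thr) at low prevalence.  AMLES relates to the relative
excess risk due to interaction by RERI = AMLES * (OR10-1)(OR01-1) when ORs
approximate RRs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenarios import Cohort, ScenarioSpec, expected_cell_probabilities

__all__ = [
    "ContingencyTable",
    "EffectEstimates",
    "ThresholdFraction",
    "tabulate",
    "oracle_table",
    "odds_ratios",
    "relative_risks",
    "amles",
    "f_est",
    "f_thr",
    "predicted_or11",
    "reri",
    "stratified_correlation",
    "ProtectiveFactorWarning",
    "DEFAULT_MIN_CELL",
    "AMLES_DENOMINATOR_EPS",
]

#: Minimum count required in every cell of the 2x2x2 table for an estimate
#: to be flagged valid.
DEFAULT_MIN_CELL = 5

#: Below this, (OR10-1)(OR01-1) is treated as zero and AMLES is undefined.
AMLES_DENOMINATOR_EPS = 1e-9


class ProtectiveFactorWarning(UserWarning):
    """A single-factor OR below 1: the AMLES scale direction flips and the
    value should be interpreted with care."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of factor patterns by outcome.

    ``counts`` has shape ``(2,) * k + (2,)`` with one leading axis per
    factor (0 absent, 1 present) and the last axis indexing outcome
    (0 control, 1 case).  Counts may be fractional (e.g. expected counts
    from the enumeration oracle).
    """

    counts: np.ndarray
    factor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        k = len(self.factor_names)
        if counts.shape != (2,) * k + (2,):
            raise ValueError(
                f"counts shape {counts.shape} does not match {k} factors"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def cell(self, pattern: tuple[int, ...], status: int) -> float:
        return float(self.counts[tuple(pattern) + (status,)])


@dataclass
class EffectEstimates:
    """Per-combination effect ratios and derived interaction scales.

    Either the OR fields or the RR fields are populated depending on which
    estimator produced the object (``scale``); the derived quantities
    (expected values, amles, f_est, reri) are computed on that scale.
    ``valid`` reports the minimum-cell filter; ratios are still reported
    when computable so that invalid rows remain auditable.
    """

    or_01: float = math.nan
    or_10: float = math.nan
    or_11: float = math.nan
    rr_01: float = math.nan
    rr_10: float = math.nan
    rr_11: float = math.nan
    expected_additive: float = math.nan
    expected_multiplicative: float = math.nan
    amles: float = math.nan
    f_est: float = math.nan
    reri: float = math.nan
    valid: bool = True
    scale: str = "or"

    #: OR00 (or RR00) is the fixed reference.
    reference: float = field(default=1.0, init=False, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "or_01": self.or_01,
            "or_10": self.or_10,
            "or_11": self.or_11,
            "rr_01": self.rr_01,
            "rr_10": self.rr_10,
            "rr_11": self.rr_11,
            "expected_additive": self.expected_additive,
            "expected_multiplicative": self.expected_multiplicative,
            "amles": self.amles,
            "f_est": self.f_est,
            "reri": self.reri,
            "valid": self.valid,
        }


@dataclass(frozen=True)
class ThresholdFraction:
    """Scaled liability threshold f_thr = (t-1)/(F-1) on [0, 1]."""

    t: int
    F: int
    value: float


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def _as_frame(cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, Cohort) else cohort


def tabulate(
    cohort: Cohort | pd.DataFrame, factor_names: list[str] | None = None
) -> ContingencyTable:
    """Count factor patterns by outcome.  Factors and status must be 0/1."""
    df = _as_frame(cohort)
    if factor_names is None:
        factor_names = (
            cohort.factor_names
            if isinstance(cohort, Cohort)
            else [c for c in df.columns if c not in ("id", "status", "group")]
        )
    missing = [c for c in factor_names if c not in df.columns]
    if missing:
        raise ValueError(f"factors not present in cohort: {missing}")
    k = len(factor_names)
    cols = [df[c].to_numpy() for c in factor_names] + [df["status"].to_numpy()]
    for name, v in zip(list(factor_names) + ["status"], cols):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"column {name!r} contains non-binary values")
    code = np.zeros(len(df), dtype=np.int64)
    for v in cols:
        code = code * 2 + v.astype(np.int64)
    counts = np.bincount(code, minlength=2 ** (k + 1)).reshape((2,) * (k + 1))
    return ContingencyTable(counts=counts.astype(float), factor_names=tuple(factor_names))


def oracle_table(spec: ScenarioSpec, total: float = 1.0) -> ContingencyTable:
    """Expected-count table from the exact enumeration oracle."""
    probs, names = expected_cell_probabilities(spec)
    return ContingencyTable(counts=probs * total, factor_names=tuple(names))


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

def amles(
    or_11: float,
    or_10: float,
    or_01: float,
    *,
    eps: float = AMLES_DENOMINATOR_EPS,
) -> float:
    """Additive-to-multiplicative linear effect scale.

    Returns NaN (the undefined-estimate signal) when the denominator
    (OR10-1)(OR01-1) is within ``eps`` of zero or any input is not finite.
    Values outside [0, 1] are legitimate (sub-additive or
    super-multiplicative joint effects).
    """
    if not all(map(math.isfinite, (or_11, or_10, or_01))):
        return math.nan
    denom = (or_10 - 1.0) * (or_01 - 1.0)
    if abs(denom) < eps:
        return math.nan
    if or_10 < 1.0 or or_01 < 1.0:
        warnings.warn(
            "single-factor effect below 1 (protective); AMLES reported but "
            "its additive/multiplicative anchors may be inverted",
            ProtectiveFactorWarning,
            stacklevel=2,
        )
    expected_additive = or_10 + or_01 - 1.0
    return (or_11 - expected_additive) / denom


def f_est(amles_value: float) -> float:
    """Signed square of AMLES: sign(AMLES) * AMLES**2."""
    if math.isnan(amles_value):
        return math.nan
    return math.copysign(amles_value * amles_value, amles_value)


def f_thr(t: int, F: int) -> ThresholdFraction:
    """Scaled threshold (t-1)/(F-1): 0 at t=1 (heterogeneity-like), 1 at
    t=F (synergism-like)."""
    if F < 2:
        raise ValueError("f_thr requires at least two components")
    if not 1 <= t <= F:
        raise ValueError(f"need 1 <= t <= F, got t={t}, F={F}")
    return ThresholdFraction(t=t, F=F, value=(t - 1) / (F - 1))


def predicted_or11(or_10: float, or_01: float, f: float) -> float:
    """Interpolated OR11 between the additive and multiplicative
    expectations with weight sqrt(f): (1-sqrt(f))*add + sqrt(f)*mult."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"threshold fraction must be in [0,1], got {f}")
    w = math.sqrt(f)
    expected_additive = or_10 + or_01 - 1.0
    expected_multiplicative = or_10 * or_01
    return (1.0 - w) * expected_additive + w * expected_multiplicative


def reri(rr_11: float, rr_10: float, rr_01: float) -> float:
    """Relative excess risk due to interaction: RR11 - RR10 - RR01 + 1."""
    return rr_11 - rr_10 - rr_01 + 1.0


# ---------------------------------------------------------------------------
# Table estimators
# ---------------------------------------------------------------------------

def _require_two_factors(table: ContingencyTable) -> None:
    if table.n_factors != 2:
        raise ValueError(
            f"pairwise estimator needs a 2-factor table, got {table.n_factors}"
        )


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.inf if num > 0 else math.nan
    return num / den


def odds_ratios(table: ContingencyTable, min_cell: int = DEFAULT_MIN_CELL) -> EffectEstimates:
    """Odds ratios per exposure combination, OR00 = 1 reference.

    ``valid`` is False when any of the eight cells falls below ``min_cell``;
    ratios are still reported when computable.
    """
    _require_two_factors(table)
    c = table.counts
    valid = bool((c >= min_cell).all())
    ref_odds = _ratio(c[0, 0, 1], c[0, 0, 0])

    def _or(x: int, z: int) -> float:
        odds = _ratio(c[x, z, 1], c[x, z, 0])
        if not math.isfinite(ref_odds) or ref_odds == 0.0 or math.isnan(odds):
            return math.nan
        return odds / ref_odds

    or_10, or_01, or_11 = _or(1, 0), _or(0, 1), _or(1, 1)
    est = EffectEstimates(
        or_10=or_10,
        or_01=or_01,
        or_11=or_11,
        expected_additive=or_10 + or_01 - 1.0,
        expected_multiplicative=or_10 * or_01,
        valid=valid,
        scale="or",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProtectiveFactorWarning)
        est.amles = amles(or_11, or_10, or_01)
    est.f_est = f_est(est.amles)
    est.reri = reri(or_11, or_10, or_01)
    return est


def relative_risks(table: ContingencyTable) -> EffectEstimates:
    """Risk ratios per exposure combination, RR00 = 1 reference.

    The population measure: appropriate for full (non-subsampled) cohorts.
    """
    _require_two_factors(table)
    c = table.counts
    totals = c.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = np.where(totals > 0, c[..., 1] / totals, np.nan)
    ref = risk[0, 0]
    valid = bool(np.isfinite(risk).all() and ref > 0)

    def _rr(x: int, z: int) -> float:
        if not ref or math.isnan(ref) or math.isnan(risk[x, z]):
            return math.nan
        return float(risk[x, z] / ref)

    rr_10, rr_01, rr_11 = _rr(1, 0), _rr(0, 1), _rr(1, 1)
    est = EffectEstimates(
        rr_10=rr_10,
        rr_01=rr_01,
        rr_11=rr_11,
        expected_additive=rr_10 + rr_01 - 1.0,
        expected_multiplicative=rr_10 * rr_01,
        valid=valid,
        scale="rr",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProtectiveFactorWarning)
        est.amles = amles(rr_11, rr_10, rr_01)
    est.f_est = f_est(est.amles)
    est.reri = reri(rr_11, rr_10, rr_01)
    return est


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return math.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(np.sum(xc * yc) / (sx * sy))


def stratified_correlation(
    cohort: Cohort | pd.DataFrame, factor_a: str, factor_b: str
) -> dict[str, float]:
    """Pearson correlation of two factors in the all/cases/controls strata.

    NaN marks strata with fewer than two individuals or a constant factor.
    """
    df = _as_frame(cohort)
    for name in (factor_a, factor_b):
        if name not in df.columns:
            raise ValueError(f"factor {name!r} not present in cohort")
    a = df[factor_a].to_numpy(dtype=float)
    b = df[factor_b].to_numpy(dtype=float)
    status = df["status"].to_numpy()
    return {
        "all": _pearson(a, b),
        "cases": _pearson(a[status == 1], b[status == 1]),
        "controls": _pearson(a[status == 0], b[status == 0]),
    }
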