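"""Replicate experiments: run many simulations per scenario and summarize.

Mirrors the study protocol: for each prevalence on a grid, many replicate
cohorts are simulated with freshly drawn factor frequencies; odds-ratio
metrics come from the equal-size subsampled cohort (the case-control view)
and risk-ratio metrics from the full cohort (the population view).  Replicate
metric vectors are summarized by median, quartiles and a percentile bootstrap
95% CI of the median, matching notched-boxplot statistics.

Randomness is organised as one master seed with per-replicate substreams
derived by a counter scheme, ``SeedSequence([seed, tag, stream, grid_index,
replicate])``, so any replicate is reproducible in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product as _iter_product

import numpy as np
import pandas as pd

from . import metrics as _m
from . import scenarios as _s

__all__ = [
    "ReplicateResult",
    "ExperimentSummary",
    "ThreeFactorFit",
    "DEFAULT_PREVALENCE_GRID",
    "run_replicate",
    "run_experiment",
    "threshold_sweep",
    "three_factor_fit",
    "correlation_sign_summary",
    "bootstrap_median_ci",
    "InvalidReplicateWarning",
]

#: Prevalences at which scenarios are evaluated by default: from the rare
#: end (0.5%, where ORs approximate RRs) to a balanced population.
DEFAULT_PREVALENCE_GRID = (0.005, 0.02, 0.10, 0.33, 0.50)

#: |median correlation| below this is reported as sign "0".
CORRELATION_DEAD_BAND = 0.01

#: Bootstrap resamples for the CI of the median.
DEFAULT_BOOTSTRAP_RESAMPLES = 1000

#: Metrics computed from the (possibly subsampled) case-control view; rows
#: failing the minimum-cell filter are excluded from their summaries.
OR_METRICS = (
    "amles",
    "f_est",
    "or_01",
    "or_10",
    "or_11",
    "expected_additive",
    "expected_multiplicative",
    "reri_or",
)

#: Metrics computed from the full population cohort or from correlations.
POPULATION_METRICS = (
    "rr_01",
    "rr_10",
    "rr_11",
    "amles_rr",
    "reri",
    "corr_all",
    "corr_cases",
    "corr_controls",
)

ALL_METRICS = OR_METRICS + POPULATION_METRICS


class InvalidReplicateWarning(UserWarning):
    """More than half of the replicates at a grid point were excluded."""


@dataclass
class ReplicateResult:
    """Metrics from one simulated cohort.

    ``or_estimates`` come from the analysis (subsampled) cohort,
    ``rr_estimates`` from the full cohort.  ``exclusion_reason`` is None for
    replicates that pass the minimum-cell filter and have a defined AMLES.
    """

    index: int
    frequencies: dict[str, float]
    realized_prevalence: float
    or_estimates: _m.EffectEstimates
    rr_estimates: _m.EffectEstimates
    correlations: dict[str, float]
    exclusion_reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.exclusion_reason is None

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"replicate": self.index}
        row.update(self.frequencies)
        row["realized_prevalence"] = self.realized_prevalence
        o, r = self.or_estimates, self.rr_estimates
        row.update(
            amles=o.amles,
            f_est=o.f_est,
            or_01=o.or_01,
            or_10=o.or_10,
            or_11=o.or_11,
            expected_additive=o.expected_additive,
            expected_multiplicative=o.expected_multiplicative,
            reri_or=o.reri,
            rr_01=r.rr_01,
            rr_10=r.rr_10,
            rr_11=r.rr_11,
            amles_rr=r.amles,
            reri=r.reri,
            corr_all=self.correlations["all"],
            corr_cases=self.correlations["cases"],
            corr_controls=self.correlations["controls"],
        )
        row["valid"] = self.valid
        row["exclusion_reason"] = self.exclusion_reason or ""
        return row


@dataclass
class ExperimentSummary:
    """Boxplot statistics for one scenario x prevalence grid point."""

    prevalence: float
    n_replicates: int
    stats: pd.DataFrame
    replicates: pd.DataFrame
    invalid_fraction: float
    high_invalid: bool = False

    def median(self, metric: str) -> float:
        return float(self.stats.loc[metric, "median"])

    def ci(self, metric: str) -> tuple[float, float]:
        return (
            float(self.stats.loc[metric, "ci_low"]),
            float(self.stats.loc[metric, "ci_high"]),
        )


def bootstrap_median_ci(
    values: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the median, resampling replicate values."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return (math.nan, math.nan)
    idx = rng.integers(0, n, size=(n_resamples, n))
    meds = np.median(values[idx], axis=1)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(meds, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def run_replicate(
    logic: _s.Logic | str,
    prevalence: float,
    rng: np.random.Generator,
    *,
    index: int = 0,
    n_components: int | None = None,
    threshold: int | None = None,
    n_individuals: int = _s.DEFAULT_N_INDIVIDUALS,
    subsample: bool = True,
    min_cell: int = _m.DEFAULT_MIN_CELL,
    group_prevalence_ratio: float = _s.DEFAULT_GROUP_PREVALENCE_RATIO,
) -> ReplicateResult:
    """Simulate one cohort with fresh frequency draws and score it."""
    spec = _s.draw_scenario(
        logic,
        prevalence,
        rng,
        n_components=n_components,
        threshold=threshold,
        n_individuals=n_individuals,
        subsample=subsample,
        group_prevalence_ratio=group_prevalence_ratio,
    )
    full = _s.simulate(spec, rng)
    pair = spec.factor_names[:2]
    full_table = _m.tabulate(full, pair)
    if subsample:
        analysis = _s.subsample_case_control(full, rng)
        or_est = _m.odds_ratios(_m.tabulate(analysis, pair), min_cell=min_cell)
    else:
        analysis = full
        or_est = _m.odds_ratios(full_table, min_cell=min_cell)
    rr_est = _m.relative_risks(full_table)
    correlations = _m.stratified_correlation(analysis, pair[0], pair[1])
    reason = None
    if not or_est.valid:
        reason = "min_cell"
    elif math.isnan(or_est.amles):
        reason = "amles_undefined"
    freqs: dict[str, float] = {}
    for f in spec.factors:
        freqs[f"{f.name}_low"] = f.low_freq
        freqs[f"{f.name}_high"] = f.high_freq
    return ReplicateResult(
        index=index,
        frequencies=freqs,
        realized_prevalence=full.realized_prevalence,
        or_estimates=or_est,
        rr_estimates=rr_est,
        correlations=correlations,
        exclusion_reason=reason,
    )


def _summarize(
    replicates: pd.DataFrame,
    prevalence: float,
    boot_rng: np.random.Generator,
    n_bootstrap: int,
) -> ExperimentSummary:
    rows = {}
    valid = replicates["valid"].to_numpy(dtype=bool)
    for metric in ALL_METRICS:
        x = replicates[metric].to_numpy(dtype=float)
        keep = np.isfinite(x)
        if metric in OR_METRICS:
            keep &= valid
        x = x[keep]
        if x.size:
            lo, hi = bootstrap_median_ci(x, boot_rng, n_resamples=n_bootstrap)
            q1, med, q3 = np.percentile(x, [25, 50, 75])
        else:
            lo = hi = q1 = med = q3 = math.nan
        rows[metric] = {
            "median": med,
            "q1": q1,
            "q3": q3,
            "ci_low": lo,
            "ci_high": hi,
            "n_used": int(x.size),
        }
    stats = pd.DataFrame.from_dict(rows, orient="index")
    invalid_fraction = float(1.0 - valid.mean()) if len(valid) else math.nan
    high_invalid = bool(invalid_fraction > 0.5)
    if high_invalid:
        warnings.warn(
            f"{invalid_fraction:.0%} of replicates at prevalence {prevalence} "
            "were excluded (min-cell filter or undefined AMLES)",
            InvalidReplicateWarning,
            stacklevel=3,
        )
    return ExperimentSummary(
        prevalence=prevalence,
        n_replicates=len(replicates),
        stats=stats,
        replicates=replicates,
        invalid_fraction=invalid_fraction,
        high_invalid=high_invalid,
    )


def run_experiment(
    logic: _s.Logic | str,
    prevalence_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    n_components: int | None = None,
    threshold: int | None = None,
    n_individuals: int = _s.DEFAULT_N_INDIVIDUALS,
    subsample: bool = True,
    min_cell: int = _m.DEFAULT_MIN_CELL,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_RESAMPLES,
    group_prevalence_ratio: float = _s.DEFAULT_GROUP_PREVALENCE_RATIO,
    _tag: int = 0,
) -> dict[float, ExperimentSummary]:
    """Replicate simulations over a prevalence grid, one summary per point."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for prev in prevalence_grid:
        if not 0.0 < prev < 1.0:
            raise ValueError(f"grid prevalence {prev} outside (0,1)")
    out: dict[float, ExperimentSummary] = {}
    for i, prev in enumerate(prevalence_grid):
        rows = []
        for k in range(n_replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, _tag, 0, i, k]))
            rep = run_replicate(
                logic,
                prev,
                rng,
                index=k,
                n_components=n_components,
                threshold=threshold,
                n_individuals=n_individuals,
                subsample=subsample,
                min_cell=min_cell,
                group_prevalence_ratio=group_prevalence_ratio,
            )
            rows.append(rep.to_row())
        replicates = pd.DataFrame(rows)
        boot_rng = np.random.default_rng(np.random.SeedSequence([seed, _tag, 1, i, 0]))
        out[prev] = _summarize(replicates, prev, boot_rng, n_bootstrap)
    return out


def threshold_sweep(
    F: int = 5,
    t_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    prevalence: float = 0.005,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    n_individuals: int = _s.DEFAULT_N_INDIVIDUALS,
    subsample: bool = True,
    min_cell: int = _m.DEFAULT_MIN_CELL,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_RESAMPLES,
) -> pd.DataFrame:
    """Median AMLES across thresholds t, with f_thr and sqrt(f_thr) overlays.

    One row per t: boxplot statistics of AMLES plus the threshold fraction
    (t-1)/(F-1) and its square root, the predicted low-prevalence median.
    """
    rows = []
    for j, t in enumerate(t_values):
        summary = run_experiment(
            _s.Logic.THRESHOLD,
            (prevalence,),
            n_replicates,
            seed,
            n_components=F,
            threshold=t,
            n_individuals=n_individuals,
            subsample=subsample,
            min_cell=min_cell,
            n_bootstrap=n_bootstrap,
            _tag=j + 1,
        )[prevalence]
        frac = _m.f_thr(t, F).value
        ci_low, ci_high = summary.ci("amles")
        rows.append(
            {
                "t": t,
                "F": F,
                "f_thr": frac,
                "sqrt_f_thr": math.sqrt(frac),
                "median_amles": summary.median("amles"),
                "q1": summary.stats.loc["amles", "q1"],
                "q3": summary.stats.loc["amles", "q3"],
                "ci_low": ci_low,
                "ci_high": ci_high,
                "n_used": summary.stats.loc["amles", "n_used"],
                "invalid_fraction": summary.invalid_fraction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Three-factor decomposition
# ---------------------------------------------------------------------------

@dataclass
class ThreeFactorFit:
    """Ranked additive/multiplicative label combinations for three factors."""

    table: pd.DataFrame
    best: tuple[str, str, str] | None
    tie: bool


def _expected_rr111(
    a: float, b: float, c: float, labels: tuple[str, str, str]
) -> float:
    """Expected RR111 for pairwise labels (XZ, XV, ZV) over RR100=a,
    RR010=b, RR001=c.

    Inclusion–exclusion composition: start from the fully additive
    a+b+c-2; each multiplicative pair contributes its two-way excess
    (r_i-1)(r_j-1); the three-way excess (a-1)(b-1)(c-1) enters only when
    all three pairs are multiplicative (then the total is exactly a*b*c).
    The fully multiplicative X arm over an additive Z/V pair reduces to
    a*(b+c-1).
    """
    l_xz, l_xv, l_zv = labels
    e = a + b + c - 2.0
    if l_xz == "mult":
        e += (a - 1.0) * (b - 1.0)
    if l_xv == "mult":
        e += (a - 1.0) * (c - 1.0)
    if l_zv == "mult":
        e += (b - 1.0) * (c - 1.0)
    if labels == ("mult", "mult", "mult"):
        e += (a - 1.0) * (b - 1.0) * (c - 1.0)
    return e


def three_factor_fit(cohort: _s.Cohort | _m.ContingencyTable) -> ThreeFactorFit:
    """Rank the eight (XZ, XV, ZV) additive/multiplicative combinations.

    Risk ratios are computed from the 2x2x2x2 table (reference: all factors
    absent); each combination's expected RR111 is compared to the observed
    one and combinations are ranked by |log(observed / expected)|.
    """
    table = cohort if isinstance(cohort, _m.ContingencyTable) else _m.tabulate(cohort)
    if table.n_factors != 3:
        raise ValueError("three_factor_fit needs exactly three factors")
    c = table.counts
    totals = c.sum(axis=-1)
    if totals[0, 0, 0] == 0 or c[0, 0, 0, 1] == 0:
        raise ValueError("reference cell (all factors absent) is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = np.where(totals > 0, c[..., 1] / totals, np.nan)
    ref = risk[0, 0, 0]
    rr = risk / ref
    a, b, cc = rr[1, 0, 0], rr[0, 1, 0], rr[0, 0, 1]
    observed = rr[1, 1, 1]
    rows = []
    for labels in _iter_product(("add", "mult"), repeat=3):
        expected = _expected_rr111(a, b, cc, labels)
        computable = (
            math.isfinite(expected)
            and math.isfinite(observed)
            and expected > 0
            and observed > 0
        )
        score = abs(math.log(observed / expected)) if computable else math.inf
        rows.append(
            {
                "xz": labels[0],
                "xv": labels[1],
                "zv": labels[2],
                "expected_rr111": expected,
                "observed_rr111": observed,
                "log_ratio_abs": score,
                "computable": computable,
            }
        )
    ranked = (
        pd.DataFrame(rows)
        .sort_values("log_ratio_abs", kind="mergesort")
        .reset_index(drop=True)
    )
    finite = ranked.loc[ranked["computable"], "log_ratio_abs"]
    tie = bool(len(finite) > 1 and (finite.max() - finite.min()) < 1e-12)
    best = None
    if len(finite) and not tie:
        top = ranked.iloc[0]
        best = (top["xz"], top["xv"], top["zv"])
    return ThreeFactorFit(table=ranked, best=best, tie=tie)


def correlation_sign_summary(
    summaries: dict[float, ExperimentSummary],
    dead_band: float = CORRELATION_DEAD_BAND,
) -> pd.DataFrame:
    """Sign (-, 0, +) of the median factor correlation per stratum and
    prevalence; |median| below ``dead_band`` counts as 0."""
    rows = {}
    for prev, summary in summaries.items():
        row = {}
        for stratum in ("all", "cases", "controls"):
            med = summary.median(f"corr_{stratum}")
            if math.isnan(med):
                row[stratum] = "na"
            elif abs(med) < dead_band:
                row[stratum] = "0"
            else:
                row[stratum] = "+" if med > 0 else "-"
        rows[prev] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("prevalence")
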