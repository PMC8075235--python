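"""Synthetic case-control cohorts under explicit causal scenarios.

Each scenario describes how a dichotomous outcome (case/control) arises from
latent binary causal sub-processes, called *components*.  A risk factor is a
binary variable (carrier / non-carrier) that is probabilistically more
frequent when its linked component is in the "present" state, so factors are
neither necessary nor sufficient for disease.  Supported scenarios:

* ``AND`` — synergism: every component must be present (same causal chain).
* ``OR`` — heterogeneity: any single component suffices (phenocopying).
* ``THRESHOLD`` — multifactorial liability threshold: at least ``t`` of ``F``
  components must be present.
* ``THREE_FACTOR`` — outcome = comp1 AND (comp2 OR comp3), a mixed structure
  used to show that multi-factor causality decomposes into pairwise scales.
* ``CONFOUNDER_I`` — cases and controls drawn from different backgrounds
  (data-reuse artefact); factors independent within each status pool.
* ``CONFOUNDER_II`` — population stratification: a mixture of two
  subpopulations differing in both factor frequencies and prevalence.
* ``ADDITIVE_O`` / ``ADDITIVE_R`` — constructions that produce exactly
  additive odds-ratio and risk-ratio relationships, respectively.

All simulators draw the exact case/control split (rounded ``n x prevalence``)
and then sample the discrete cell states *conditional on outcome* from the
closed-form cell probabilities, so the realized prevalence is controlled to
rounding error rather than binomial noise.  The same closed form is exposed
as :func:`expected_cell_probabilities` and serves as an exact enumeration
oracle in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import product as _iter_product

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

__all__ = [
    "Logic",
    "FactorSpec",
    "ScenarioSpec",
    "Cohort",
    "draw_factor_frequencies",
    "draw_scenario",
    "solve_component_probability",
    "simulate",
    "simulate_population",
    "simulate_three_factor",
    "simulate_confounder_i",
    "simulate_confounder_ii",
    "simulate_additive_scheme",
    "subsample_case_control",
    "expected_cell_probabilities",
    "PrevalenceToleranceWarning",
]

#: Default cohort size per simulation run.
DEFAULT_N_INDIVIDUALS = 1_000_000

#: Default absolute tolerance on the realized case fraction.
DEFAULT_PREVALENCE_TOLERANCE = 4e-4

#: Upper clip applied when a frequency multiplier would push a factor
#: frequency to 1 or above.
HIGH_FREQ_CLIP = 0.99

#: Frequency-draw protocol per factor role: (low-frequency range,
#: multiplier range).  The low frequency is uniform on its range and the
#: high frequency is low x multiplier.
FREQUENCY_PROTOCOL = {
    "Z-like": ((0.05, 0.15), (1.1, 4.0)),
    "X-like": ((0.05, 0.25), (1.1, 2.0)),
}

#: Default ratio between subpopulation prevalences in the stratification
#: (confounder II) scenario.
DEFAULT_GROUP_PREVALENCE_RATIO = 4.0


class PrevalenceToleranceWarning(UserWarning):
    """Realized case fraction deviates from the target beyond tolerance."""


class Logic(str, Enum):
    """Causal logic wiring components (or pools/groups) to the outcome."""

    AND = "and"
    OR = "or"
    THRESHOLD = "threshold"
    THREE_FACTOR = "three-factor"
    CONFOUNDER_I = "confounder1"
    CONFOUNDER_II = "confounder2"
    ADDITIVE_O = "additive-o"
    ADDITIVE_R = "additive-r"


#: Logics in which factors attach to latent components.
COMPONENT_LOGICS = frozenset({Logic.AND, Logic.OR, Logic.THRESHOLD, Logic.THREE_FACTOR})


@dataclass(frozen=True)
class FactorSpec:
    """A dichotomous risk factor.

    ``low_freq`` is the carrier frequency when the linked component is absent
    (or, for the pool/mixture scenarios, in the low-risk pool/group);
    ``high_freq`` when it is present.  ``linked_component`` indexes the
    component the factor tracks, or ``None`` for scenarios without
    components.  ``clipped`` records that the protocol multiplier pushed the
    high frequency to the clip ceiling.
    """

    name: str
    low_freq: float
    high_freq: float
    linked_component: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.low_freq <= self.high_freq < 1.0):
            raise ValueError(
                f"factor {self.name!r}: need 0 < low_freq <= high_freq < 1, "
                f"got ({self.low_freq}, {self.high_freq})"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one causal scenario.

    Parameters
    ----------
    logic
        Scenario family (see :class:`Logic`).
    factors
        The observed risk factors.  Component logics require every factor to
        link to a component index in ``range(n_components)``.
    prevalence
        Target case fraction in the full (pre-subsampling) cohort.
    n_components
        Number of latent components ``F`` (component logics only).
    threshold
        Liability threshold ``t`` with ``1 <= t <= F`` (THRESHOLD only).
    subsample
        Whether analyses downstream should subsample controls to the case
        count (case-control design); the simulators themselves always return
        the full cohort.
    group_prevalence_ratio
        Prevalence ratio between the two subpopulations (CONFOUNDER_II only).
    """

    logic: Logic
    factors: tuple[FactorSpec, ...]
    prevalence: float
    n_components: int = 2
    threshold: int | None = None
    prevalence_tolerance: float = DEFAULT_PREVALENCE_TOLERANCE
    n_individuals: int = DEFAULT_N_INDIVIDUALS
    subsample: bool = True
    group_prevalence_ratio: float = DEFAULT_GROUP_PREVALENCE_RATIO

    def __post_init__(self) -> None:
        object.__setattr__(self, "logic", Logic(self.logic))
        object.__setattr__(self, "factors", tuple(self.factors))
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.prevalence_tolerance <= 0:
            raise ValueError("prevalence_tolerance must be positive")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if len(self.factors) == 0:
            raise ValueError("at least one factor is required")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if self.logic in COMPONENT_LOGICS:
            if self.n_components < 1:
                raise ValueError("n_components must be >= 1")
            for f in self.factors:
                if f.linked_component is None or not (
                    0 <= f.linked_component < self.n_components
                ):
                    raise ValueError(
                        f"factor {f.name!r} must link to a component in "
                        f"range({self.n_components})"
                    )
        if self.logic is Logic.THRESHOLD:
            if self.threshold is None or not (1 <= self.threshold <= self.n_components):
                raise ValueError("THRESHOLD requires 1 <= t <= n_components")
        if self.logic is Logic.THREE_FACTOR:
            if len(self.factors) != 3 or self.n_components != 3:
                raise ValueError("THREE_FACTOR requires exactly 3 factors/components")
        if self.logic in (Logic.AND, Logic.OR) and len(self.factors) == 2:
            if self.n_components != 2:
                raise ValueError("two-factor AND/OR scenarios require F = 2")
        if self.logic is Logic.CONFOUNDER_II and self.group_prevalence_ratio <= 0:
            raise ValueError("group_prevalence_ratio must be positive")

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]


@dataclass
class Cohort:
    """Simulated individuals: binary factor values plus case/control status.

    ``data`` holds one row per individual with a ``status`` column
    (0 control, 1 case), one 0/1 column per factor, and an optional
    ``group`` column for mixture scenarios.
    """

    data: pd.DataFrame
    spec: ScenarioSpec | None = None

    RESERVED: tuple[str, ...] = field(
        default=("id", "status", "group"), init=False, repr=False
    )

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def realized_prevalence(self) -> float:
        return self.n_cases / self.n if self.n else float("nan")


# ---------------------------------------------------------------------------
# Frequency-draw protocol
# ---------------------------------------------------------------------------

def draw_factor_frequencies(
    role: str, rng: np.random.Generator
) -> tuple[float, float, bool]:
    """Draw (low_freq, high_freq, clipped) for a factor of the given role.

    "Z-like" factors draw the low frequency uniformly on [0.05, 0.15] and
    multiply by a uniform [1.1, 4] factor for the high frequency; "X-like"
    factors use [0.05, 0.25] and a [1.1, 2] multiplier.  The high frequency
    is clipped at :data:`HIGH_FREQ_CLIP`; ``clipped`` records when that
    happened.
    """
    try:
        (lo, hi), (mlo, mhi) = FREQUENCY_PROTOCOL[role]
    except KeyError:
        raise ValueError(
            f"unknown factor role {role!r}; expected one of {sorted(FREQUENCY_PROTOCOL)}"
        ) from None
    low = float(rng.uniform(lo, hi))
    high = low * float(rng.uniform(mlo, mhi))
    clipped = high >= HIGH_FREQ_CLIP
    if clipped:
        high = HIGH_FREQ_CLIP
    return low, high, clipped


def draw_scenario(
    logic: Logic | str,
    prevalence: float,
    rng: np.random.Generator,
    *,
    n_components: int | None = None,
    threshold: int | None = None,
    n_individuals: int = DEFAULT_N_INDIVIDUALS,
    subsample: bool = True,
    group_prevalence_ratio: float = DEFAULT_GROUP_PREVALENCE_RATIO,
) -> ScenarioSpec:
    """Build a ScenarioSpec with freshly drawn factor frequencies.

    The conventional factor layout is used: an X-like factor ``X`` and a
    Z-like factor ``Z`` (plus a second Z-like factor ``V`` for the
    three-factor scenario), linked to the first components where the logic
    has components.
    """
    logic = Logic(logic)
    if n_components is None:
        n_components = 3 if logic is Logic.THREE_FACTOR else (
            5 if logic is Logic.THRESHOLD else 2
        )

    def _factor(name: str, role: str, comp: int | None) -> FactorSpec:
        low, high, clipped = draw_factor_frequencies(role, rng)
        return FactorSpec(name, low, high, linked_component=comp, clipped=clipped)

    in_components = logic in COMPONENT_LOGICS
    factors = [
        _factor("X", "X-like", 0 if in_components else None),
        _factor("Z", "Z-like", 1 if in_components else None),
    ]
    if logic is Logic.THREE_FACTOR:
        factors.append(_factor("V", "Z-like", 2))
    return ScenarioSpec(
        logic=logic,
        factors=tuple(factors),
        prevalence=prevalence,
        n_components=n_components,
        threshold=threshold,
        n_individuals=n_individuals,
        subsample=subsample,
        group_prevalence_ratio=group_prevalence_ratio,
    )


# ---------------------------------------------------------------------------
# Component probability <-> prevalence mapping
# ---------------------------------------------------------------------------

def solve_component_probability(
    logic: Logic | str,
    n_components: int,
    threshold: int | None,
    prevalence: float,
) -> float:
    """Per-component present-probability giving the target outcome prevalence.

    Components are exchangeable (equal probability ``p``), so the mapping is
    closed-form for AND (``p = prevalence**(1/F)``) and OR
    (``p = 1 - (1-prevalence)**(1/F)``) and a one-dimensional root find on
    ``P(Binomial(F, p) >= t) = prevalence`` for the threshold logic.
    """
    logic = Logic(logic)
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    F = n_components
    if logic is Logic.AND:
        return float(prevalence ** (1.0 / F))
    if logic is Logic.OR:
        return float(1.0 - (1.0 - prevalence) ** (1.0 / F))
    if logic is Logic.THRESHOLD:
        t = threshold
        if t is None or not 1 <= t <= F:
            raise ValueError("need 1 <= t <= F")
        # P(Bin(F,p) >= t) is strictly increasing in p from 0 to 1.
        fun = lambda p: binom.sf(t - 1, F, p) - prevalence
        return float(brentq(fun, 1e-15, 1.0 - 1e-15, xtol=1e-14, rtol=1e-15))
    raise ValueError(f"no component-probability mapping for logic {logic}")


def _three_factor_probs(prevalence: float) -> np.ndarray:
    """Component probabilities for outcome = c1 AND (c2 OR c3).

    Components 2 and 3 share probability q and component 1 matches the OR
    combination of the other two, p1 = 1-(1-q)^2, so prevalence = p1^2.
    """
    p1 = float(np.sqrt(prevalence))
    q = 1.0 - float(np.sqrt(1.0 - p1))
    return np.array([p1, q, q])


# ---------------------------------------------------------------------------
# Closed-form cell probabilities (the enumeration oracle)
# ---------------------------------------------------------------------------

def _component_patterns(F: int) -> np.ndarray:
    return np.array(list(_iter_product((0, 1), repeat=F)), dtype=np.int8)


def _pattern_probs(patterns: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.prod(np.where(patterns == 1, p, 1.0 - p), axis=1)


def _outcome_of_patterns(spec: ScenarioSpec, patterns: np.ndarray) -> np.ndarray:
    logic = spec.logic
    if logic is Logic.AND:
        return patterns.all(axis=1)
    if logic is Logic.OR:
        return patterns.any(axis=1)
    if logic is Logic.THRESHOLD:
        return patterns.sum(axis=1) >= spec.threshold
    if logic is Logic.THREE_FACTOR:
        return (patterns[:, 0] == 1) & ((patterns[:, 1] == 1) | (patterns[:, 2] == 1))
    raise ValueError(f"logic {logic} has no component patterns")


def _component_probs(spec: ScenarioSpec) -> np.ndarray:
    if spec.logic is Logic.THREE_FACTOR:
        return _three_factor_probs(spec.prevalence)
    p = solve_component_probability(
        spec.logic, spec.n_components, spec.threshold, spec.prevalence
    )
    return np.full(spec.n_components, p)


def _bern(freq: float, value: np.ndarray) -> np.ndarray:
    return np.where(value == 1, freq, 1.0 - freq)


def _additive_r_params(spec: ScenarioSpec) -> tuple[float, np.ndarray, np.ndarray]:
    """Baseline risk and per-factor (frequency, relative-risk) for ADDITIVE_R.

    Factors occur at their low frequency; the high/low ratio acts as the
    factor's relative risk on a linear-probability scale:
    P(case | x) = p0 * (1 + sum_i (r_i - 1) x_i).
    """
    freqs = np.array([f.low_freq for f in spec.factors])
    rrs = np.array([f.high_freq / f.low_freq for f in spec.factors])
    p0 = spec.prevalence / (1.0 + np.sum((rrs - 1.0) * freqs))
    if p0 * (1.0 + np.sum(rrs - 1.0)) >= 1.0:
        raise ValueError(
            "linear-risk scheme needs p0 + sum of risk increments < 1; "
            "lower the prevalence or the frequency multipliers"
        )
    return float(p0), freqs, rrs


def _confounder_ii_prevalences(spec: ScenarioSpec) -> tuple[float, float]:
    r = spec.group_prevalence_ratio
    p_a = 2.0 * spec.prevalence / (1.0 + r)
    p_b = r * p_a
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError(
            "subpopulation prevalences fall outside (0,1); "
            "adjust prevalence or group_prevalence_ratio"
        )
    return p_a, p_b


def expected_cell_probabilities(spec: ScenarioSpec) -> tuple[np.ndarray, list[str]]:
    """Exact joint probabilities P(factor pattern, status) for a scenario.

    Returns ``(probs, factor_names)`` where ``probs`` has shape
    ``(2,) * k + (2,)`` with the last axis indexing status (0 control,
    1 case) and sums to 1.  Computed by summing over all latent states
    (component patterns, pools or groups), independent of any simulation.
    """
    k = len(spec.factors)
    names = spec.factor_names
    shape = (2,) * k + (2,)
    probs = np.zeros(shape)
    xpatterns = np.array(list(_iter_product((0, 1), repeat=k)), dtype=np.int8)

    if spec.logic in COMPONENT_LOGICS:
        patterns = _component_patterns(spec.n_components)
        pprob = _pattern_probs(patterns, _component_probs(spec))
        outcome = _outcome_of_patterns(spec, patterns)
        for x in xpatterns:
            # P(x | component pattern) factorises over factors
            px_given_s = np.ones(len(patterns))
            for j, f in enumerate(spec.factors):
                present = patterns[:, f.linked_component] == 1
                freq = np.where(present, f.high_freq, f.low_freq)
                px_given_s *= np.where(x[j] == 1, freq, 1.0 - freq)
            idx = tuple(x)
            probs[idx + (1,)] = np.sum(pprob[outcome] * px_given_s[outcome])
            probs[idx + (0,)] = np.sum(pprob[~outcome] * px_given_s[~outcome])
        return probs, names

    prev = spec.prevalence
    if spec.logic is Logic.CONFOUNDER_I:
        for x in xpatterns:
            case = np.prod([_bern(f.high_freq, x[j]) for j, f in enumerate(spec.factors)])
            ctrl = np.prod([_bern(f.low_freq, x[j]) for j, f in enumerate(spec.factors)])
            probs[tuple(x) + (1,)] = prev * case
            probs[tuple(x) + (0,)] = (1.0 - prev) * ctrl
        return probs, names

    if spec.logic is Logic.CONFOUNDER_II:
        p_a, p_b = _confounder_ii_prevalences(spec)
        for x in xpatterns:
            for g, pg in ((0, p_a), (1, p_b)):
                fx = np.prod(
                    [
                        _bern(f.low_freq if g == 0 else f.high_freq, x[j])
                        for j, f in enumerate(spec.factors)
                    ]
                )
                probs[tuple(x) + (1,)] += 0.5 * pg * fx
                probs[tuple(x) + (0,)] += 0.5 * (1.0 - pg) * fx
        return probs, names

    if spec.logic is Logic.ADDITIVE_O:
        if k != 2:
            raise ValueError("ADDITIVE_O is defined for exactly two factors")
        fx, fz = spec.factors
        for x in xpatterns:
            for status in (0, 1):
                # group 0: Z causal, X at its low frequency in both strata
                z_freq = fz.high_freq if status == 1 else fz.low_freq
                g0 = _bern(fx.low_freq, x[0]) * _bern(z_freq, x[1])
                # group 1: X causal, Z at its low frequency
                x_freq = fx.high_freq if status == 1 else fx.low_freq
                g1 = _bern(x_freq, x[0]) * _bern(fz.low_freq, x[1])
                p_status = prev if status == 1 else 1.0 - prev
                probs[tuple(x) + (status,)] = p_status * 0.5 * (g0 + g1)
        return probs, names

    if spec.logic is Logic.ADDITIVE_R:
        p0, freqs, rrs = _additive_r_params(spec)
        for x in xpatterns:
            px = np.prod([_bern(freqs[j], x[j]) for j in range(k)])
            risk = p0 * (1.0 + np.sum((rrs - 1.0) * x))
            probs[tuple(x) + (1,)] = px * risk
            probs[tuple(x) + (0,)] = px * (1.0 - risk)
        return probs, names

    raise ValueError(f"unknown logic {spec.logic}")


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _split_counts(spec: ScenarioSpec) -> tuple[int, int]:
    n = spec.n_individuals
    n_cases = int(round(n * spec.prevalence))
    if n_cases == 0 or n_cases == n:
        raise ValueError(
            f"n_individuals={n} too small for prevalence {spec.prevalence}"
        )
    deviation = abs(n_cases / n - spec.prevalence)
    if deviation > spec.prevalence_tolerance:
        warnings.warn(
            f"realized prevalence deviates by {deviation:.2e} from target "
            f"{spec.prevalence} (tolerance {spec.prevalence_tolerance}) at "
            f"n_individuals={n}",
            PrevalenceToleranceWarning,
            stacklevel=3,
        )
    return n_cases, n - n_cases


def _assemble(parts: list[pd.DataFrame], spec: ScenarioSpec) -> Cohort:
    data = pd.concat(parts, ignore_index=True)
    return Cohort(data=data, spec=spec)


def _simulate_components(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    patterns = _component_patterns(spec.n_components)
    pprob = _pattern_probs(patterns, _component_probs(spec))
    outcome = _outcome_of_patterns(spec, patterns)
    n_cases, n_controls = _split_counts(spec)
    parts = []
    for status, n_class in ((1, n_cases), (0, n_controls)):
        mask = outcome if status == 1 else ~outcome
        cls_probs = pprob[mask]
        total = cls_probs.sum()
        if total <= 0.0:
            raise ValueError(f"outcome class {status} has zero probability")
        counts = rng.multinomial(n_class, cls_probs / total)
        row_idx = np.repeat(np.flatnonzero(mask), counts)
        cols: dict[str, np.ndarray] = {
            "status": np.full(row_idx.size, status, dtype=np.int8)
        }
        for f in spec.factors:
            present = patterns[row_idx, f.linked_component] == 1
            freq = np.where(present, f.high_freq, f.low_freq)
            cols[f.name] = (rng.random(row_idx.size) < freq).astype(np.int8)
        parts.append(pd.DataFrame(cols))
    return _assemble(parts, spec)


def simulate_population(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    """Simulate a cohort under the AND, OR or THRESHOLD component logic."""
    if spec.logic not in (Logic.AND, Logic.OR, Logic.THRESHOLD):
        raise ValueError(f"simulate_population does not handle {spec.logic}")
    return _simulate_components(spec, rng)


def simulate_three_factor(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    """Simulate outcome = comp1 AND (comp2 OR comp3) with factors X, Z, V."""
    if spec.logic is not Logic.THREE_FACTOR:
        raise ValueError("spec.logic must be THREE_FACTOR")
    return _simulate_components(spec, rng)


def simulate_confounder_i(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    """Cases and controls as two separate pools with different backgrounds.

    Within each pool the factors are drawn independently; cases use the high
    frequencies, controls the low ones.  Because the factors are independent
    conditional on status, the expected odds ratios are exactly
    multiplicative at any case fraction.
    """
    if spec.logic is not Logic.CONFOUNDER_I:
        raise ValueError("spec.logic must be CONFOUNDER_I")
    n_cases, n_controls = _split_counts(spec)
    parts = []
    for status, n_class in ((1, n_cases), (0, n_controls)):
        cols = {"status": np.full(n_class, status, dtype=np.int8)}
        for f in spec.factors:
            freq = f.high_freq if status == 1 else f.low_freq
            cols[f.name] = (rng.random(n_class) < freq).astype(np.int8)
        parts.append(pd.DataFrame(cols))
    return _assemble(parts, spec)


def simulate_confounder_ii(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    """Equal mixture of two subpopulations with different frequencies and
    prevalences (population stratification); factors independent of status
    within each subpopulation.  The ``group`` column records membership."""
    if spec.logic is not Logic.CONFOUNDER_II:
        raise ValueError("spec.logic must be CONFOUNDER_II")
    p_a, p_b = _confounder_ii_prevalences(spec)
    n_cases, n_controls = _split_counts(spec)
    parts = []
    for status, n_class in ((1, n_cases), (0, n_controls)):
        # P(group B | status) from Bayes with equal group weights
        wa = p_a if status == 1 else 1.0 - p_a
        wb = p_b if status == 1 else 1.0 - p_b
        group = (rng.random(n_class) < wb / (wa + wb)).astype(np.int8)
        cols = {"status": np.full(n_class, status, dtype=np.int8), "group": group}
        for f in spec.factors:
            freq = np.where(group == 1, f.high_freq, f.low_freq)
            cols[f.name] = (rng.random(n_class) < freq).astype(np.int8)
        parts.append(pd.DataFrame(cols))
    return _assemble(parts, spec)


def simulate_additive_scheme(
    variant: str, spec: ScenarioSpec, rng: np.random.Generator
) -> Cohort:
    """Simulate one of the two purpose-built additive schemes.

    Variant ``"R"`` uses a linear-probability risk model, which makes the
    expected risk ratios exactly additive (RR11 = RR10 + RR01 - 1).  Variant
    ``"O"`` splits individuals into two equal groups in which only one of
    the two factors carries risk (the other stays at its control frequency);
    this makes the expected odds ratios exactly additive at any case
    fraction.
    """
    variant = variant.upper()
    if variant == "R":
        if spec.logic is not Logic.ADDITIVE_R:
            raise ValueError("variant R requires spec.logic ADDITIVE_R")
        p0, freqs, rrs = _additive_r_params(spec)
        probs, names = expected_cell_probabilities(spec)
        k = len(names)
        xpatterns = np.array(list(_iter_product((0, 1), repeat=k)), dtype=np.int8)
        n_cases, n_controls = _split_counts(spec)
        parts = []
        for status, n_class in ((1, n_cases), (0, n_controls)):
            cell_p = np.array([probs[tuple(x) + (status,)] for x in xpatterns])
            counts = rng.multinomial(n_class, cell_p / cell_p.sum())
            rows = np.repeat(np.arange(len(xpatterns)), counts)
            cols = {"status": np.full(rows.size, status, dtype=np.int8)}
            for j, name in enumerate(names):
                cols[name] = xpatterns[rows, j]
            parts.append(pd.DataFrame(cols))
        return _assemble(parts, spec)
    if variant == "O":
        if spec.logic is not Logic.ADDITIVE_O:
            raise ValueError("variant O requires spec.logic ADDITIVE_O")
        if len(spec.factors) != 2:
            raise ValueError("ADDITIVE_O is defined for exactly two factors")
        fx, fz = spec.factors
        n_cases, n_controls = _split_counts(spec)
        parts = []
        for status, n_class in ((1, n_cases), (0, n_controls)):
            group = (rng.random(n_class) < 0.5).astype(np.int8)
            # group 0: only Z causal; group 1: only X causal
            z_freq = np.where(
                group == 0, fz.high_freq if status == 1 else fz.low_freq, fz.low_freq
            )
            x_freq = np.where(
                group == 1, fx.high_freq if status == 1 else fx.low_freq, fx.low_freq
            )
            cols = {
                "status": np.full(n_class, status, dtype=np.int8),
                fx.name: (rng.random(n_class) < x_freq).astype(np.int8),
                fz.name: (rng.random(n_class) < z_freq).astype(np.int8),
                "group": group,
            }
            parts.append(pd.DataFrame(cols))
        return _assemble(parts, spec)
    raise ValueError(f"unknown additive variant {variant!r}; use 'O' or 'R'")


_DISPATCH = {
    Logic.AND: simulate_population,
    Logic.OR: simulate_population,
    Logic.THRESHOLD: simulate_population,
    Logic.THREE_FACTOR: simulate_three_factor,
    Logic.CONFOUNDER_I: simulate_confounder_i,
    Logic.CONFOUNDER_II: simulate_confounder_ii,
    Logic.ADDITIVE_O: lambda spec, rng: simulate_additive_scheme("O", spec, rng),
    Logic.ADDITIVE_R: lambda spec, rng: simulate_additive_scheme("R", spec, rng),
}


def simulate(spec: ScenarioSpec, rng: np.random.Generator) -> Cohort:
    """Simulate a full (non-subsampled) cohort for any scenario logic."""
    return _DISPATCH[spec.logic](spec, rng)


def subsample_case_control(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Keep all cases; downsample controls uniformly to the case count.

    Mimics the biased sampling of a case-control study.  Odds ratios are
    invariant to this in expectation; correlations between risk factors in
    the combined stratum are not.
    """
    status = cohort.data["status"].to_numpy()
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    if case_idx.size < 1:
        raise ValueError("cohort has no cases")
    if ctrl_idx.size < case_idx.size:
        raise ValueError(
            f"cannot subsample: {ctrl_idx.size} controls < {case_idx.size} cases"
        )
    keep_ctrl = rng.choice(ctrl_idx, size=case_idx.size, replace=False)
    keep = np.sort(np.concatenate([case_idx, keep_ctrl]))
    data = cohort.data.iloc[keep].reset_index(drop=True)
    return Cohort(data=data, spec=cohort.spec)
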