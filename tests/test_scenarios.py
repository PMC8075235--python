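"""Tests for the causal-scenario simulators and their enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

import amles
from amles import scenarios as s
from amles import metrics as m

from conftest import make_pair_spec, oracle_agreement


# ---------------------------------------------------------------------------
# Frequency-draw protocol
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "role, low_range, mult_range",
    [("Z-like", (0.05, 0.15), (1.1, 4.0)), ("X-like", (0.05, 0.25), (1.1, 2.0))],
)
def test_frequency_draw_ranges(role, low_range, mult_range, rng):
    for _ in range(200):
        low, high, clipped = s.draw_factor_frequencies(role, rng)
        assert low_range[0] <= low <= low_range[1]
        assert not clipped
        ratio = high / low
        assert mult_range[0] - 1e-12 <= ratio <= mult_range[1] + 1e-12


def test_frequency_draw_reproducible():
    a = s.draw_factor_frequencies("Z-like", np.random.default_rng(7))
    b = s.draw_factor_frequencies("Z-like", np.random.default_rng(7))
    assert a == b


def test_frequency_draw_unknown_role(rng):
    with pytest.raises(ValueError, match="unknown factor role"):
        s.draw_factor_frequencies("Y-like", rng)


# ---------------------------------------------------------------------------
# Component probability mapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "logic, F, t, prevalence, expected",
    [
        (s.Logic.AND, 2, None, 0.25, 0.5),
        (s.Logic.OR, 2, None, 0.75, 0.5),
        (s.Logic.THRESHOLD, 5, 3, 0.5, 0.5),
    ],
)
def test_component_probability_closed_forms(logic, F, t, prevalence, expected):
    assert s.solve_component_probability(logic, F, t, prevalence) == pytest.approx(
        expected, abs=1e-10
    )


@pytest.mark.parametrize("t", [1, 2, 3, 4, 5])
def test_threshold_probability_roundtrip(t):
    from scipy.stats import binom

    p = s.solve_component_probability(s.Logic.THRESHOLD, 5, t, 0.005)
    assert binom.sf(t - 1, 5, p) == pytest.approx(0.005, abs=1e-10)


def test_threshold_matches_or_and_closed_forms():
    # t=1 is the any-component logic, t=F the all-components logic
    p_or = s.solve_component_probability(s.Logic.OR, 2, None, 0.005)
    p_t1 = s.solve_component_probability(s.Logic.THRESHOLD, 2, 1, 0.005)
    p_and = s.solve_component_probability(s.Logic.AND, 2, None, 0.005)
    p_t2 = s.solve_component_probability(s.Logic.THRESHOLD, 2, 2, 0.005)
    assert p_t1 == pytest.approx(p_or, abs=1e-12)
    assert p_t2 == pytest.approx(p_and, abs=1e-12)


def test_component_probability_rejects_bad_input():
    with pytest.raises(ValueError):
        s.solve_component_probability(s.Logic.AND, 2, None, 1.5)
    with pytest.raises(ValueError):
        s.solve_component_probability(s.Logic.THRESHOLD, 5, 0, 0.1)


# ---------------------------------------------------------------------------
# Spec validation
# ---------------------------------------------------------------------------

def test_factor_spec_validation():
    with pytest.raises(ValueError):
        s.FactorSpec("X", 0.3, 0.2)  # low > high
    with pytest.raises(ValueError):
        s.FactorSpec("X", 0.0, 0.2)


def test_scenario_spec_validation():
    f = (s.FactorSpec("X", 0.1, 0.2, 0), s.FactorSpec("Z", 0.1, 0.2, 1))
    with pytest.raises(ValueError, match="prevalence"):
        s.ScenarioSpec(logic=s.Logic.AND, factors=f, prevalence=0.0)
    with pytest.raises(ValueError, match="1 <= t"):
        s.ScenarioSpec(logic=s.Logic.THRESHOLD, factors=f, prevalence=0.1,
                       n_components=2, threshold=3)
    with pytest.raises(ValueError, match="THREE_FACTOR"):
        s.ScenarioSpec(logic=s.Logic.THREE_FACTOR, factors=f, prevalence=0.1,
                       n_components=3)
    with pytest.raises(ValueError, match="unique"):
        s.ScenarioSpec(
            logic=s.Logic.AND,
            factors=(s.FactorSpec("X", 0.1, 0.2, 0), s.FactorSpec("X", 0.1, 0.2, 1)),
            prevalence=0.1,
        )


# ---------------------------------------------------------------------------
# Simulators vs the enumeration oracle
# ---------------------------------------------------------------------------

def _spec_for(logic, rng):
    if logic == "three-factor":
        return s.draw_scenario(logic, 0.005, rng, n_individuals=100_000)
    if logic.startswith("threshold"):
        t = int(logic.split(":")[1])
        return s.draw_scenario("threshold", 0.005, rng, n_components=5,
                               threshold=t, n_individuals=100_000)
    prevalence = 0.1 if logic.startswith(("confounder", "additive")) else 0.005
    return s.draw_scenario(logic, prevalence, rng, n_individuals=100_000)


@pytest.mark.parametrize(
    "logic",
    ["and", "or", "threshold:1", "threshold:2", "threshold:3", "threshold:4",
     "threshold:5", "three-factor", "confounder1", "confounder2",
     "additive-o", "additive-r"],
)
def test_oracle_matches_simulation(logic, rng):
    spec = _spec_for(logic, rng)
    max_z, _ = oracle_agreement(spec, rng)
    assert max_z < 4.0


def test_null_factors_show_no_association(rng):
    # high_freq == low_freq: factors carry no information about the outcome
    spec = make_pair_spec("and", prevalence=0.05, fx=(0.2, 0.2), fz=(0.3, 0.3))
    cohort = s.simulate(spec, rng)
    est = m.relative_risks(m.tabulate(cohort, ["X", "Z"]))
    for v in (est.rr_10, est.rr_01, est.rr_11):
        assert v == pytest.approx(1.0, abs=0.15)


@pytest.mark.parametrize("prevalence", [0.005, 0.1, 0.33, 0.5])
def test_and_oracle_risk_ratios_multiplicative(prevalence):
    # synergism: RR11 = RR10 x RR01 exactly, at every prevalence
    spec = make_pair_spec("and", prevalence=prevalence)
    est = m.relative_risks(amles.oracle_table(spec))
    assert est.rr_11 == pytest.approx(est.rr_10 * est.rr_01, rel=1e-9)


def test_or_oracle_additive_low_prevalence_subadditive_high():
    low = m.relative_risks(amles.oracle_table(make_pair_spec("or", 0.001)))
    high = m.relative_risks(amles.oracle_table(make_pair_spec("or", 0.5)))
    assert low.reri == pytest.approx(0.0, abs=0.01)
    assert high.reri < -0.01  # less than additive at high prevalence


def test_seed_determinism():
    spec = make_pair_spec("and", n=10_000)
    a = s.simulate(spec, np.random.default_rng(3)).data
    b = s.simulate(spec, np.random.default_rng(3)).data
    pd.testing.assert_frame_equal(a, b)


def test_prevalence_control_is_exact(rng):
    spec = make_pair_spec("or", prevalence=0.005, n=100_000)
    cohort = s.simulate(spec, rng)
    assert cohort.realized_prevalence == pytest.approx(0.005, abs=4e-4)


def test_unattainable_tolerance_warns():
    spec = make_pair_spec("and", prevalence=0.024, n=100)
    with pytest.warns(s.PrevalenceToleranceWarning):
        s.simulate(spec, np.random.default_rng(0))


def test_too_small_cohort_rejected():
    spec = make_pair_spec("and", prevalence=0.001, n=100)
    with pytest.raises(ValueError, match="too small"):
        s.simulate(spec, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def test_subsample_equalizes_counts(rng):
    data = pd.DataFrame({
        "status": np.r_[np.ones(100, dtype=np.int8), np.zeros(900, dtype=np.int8)],
        "X": np.zeros(1000, dtype=np.int8),
        "Z": np.zeros(1000, dtype=np.int8),
    })
    sub = s.subsample_case_control(s.Cohort(data=data), rng)
    assert sub.n_cases == 100 and sub.n == 200


def test_subsample_rejects_short_controls(rng):
    data = pd.DataFrame({"status": np.r_[np.ones(10), np.zeros(5)].astype(np.int8),
                         "X": np.zeros(15, dtype=np.int8)})
    with pytest.raises(ValueError, match="cannot subsample"):
        s.subsample_case_control(s.Cohort(data=data), rng)


def test_and_subsampling_induces_positive_combined_correlation(rng):
    # biased case-control sampling correlates the risk factors in "all"
    spec = make_pair_spec("and", prevalence=0.01, n=400_000,
                          fx=(0.20, 0.40), fz=(0.10, 0.40))
    cohort = s.simulate(spec, rng)
    full_corr = m.stratified_correlation(cohort, "X", "Z")
    sub = s.subsample_case_control(cohort, rng)
    sub_corr = m.stratified_correlation(sub, "X", "Z")
    assert abs(full_corr["all"]) < 0.02
    assert sub_corr["all"] > 0.02


def test_heterogeneity_negative_case_correlation(rng):
    # competing sufficient pathways anticorrelate the factors among cases
    spec = make_pair_spec("or", prevalence=0.01, n=400_000,
                          fx=(0.15, 0.30), fz=(0.10, 0.40))
    cohort = s.simulate(spec, rng)
    corr = m.stratified_correlation(cohort, "X", "Z")
    assert corr["cases"] < -0.01
    assert abs(corr["controls"]) < 0.01


# ---------------------------------------------------------------------------
# Confounder scenarios
# ---------------------------------------------------------------------------

def test_confounder_i_oracle_exactly_multiplicative():
    for cf in (0.1, 0.3, 0.5, 0.8):
        spec = make_pair_spec("confounder1", prevalence=cf)
        est = m.odds_ratios(amles.oracle_table(spec), min_cell=0)
        assert est.or_11 == pytest.approx(est.or_10 * est.or_01, rel=1e-12)


def test_confounder_i_independent_within_status(rng):
    spec = make_pair_spec("confounder1", prevalence=0.3, n=200_000)
    corr = m.stratified_correlation(s.simulate(spec, rng), "X", "Z")
    assert abs(corr["cases"]) < 0.01
    assert abs(corr["controls"]) < 0.01


def test_confounder_ii_positive_correlation_all_strata(rng):
    spec = make_pair_spec("confounder2", prevalence=0.1, n=400_000,
                          fx=(0.10, 0.30), fz=(0.10, 0.35))
    corr = m.stratified_correlation(s.simulate(spec, rng), "X", "Z")
    assert all(v > 0 for v in corr.values())


def test_confounder_ii_degenerate_mixture_is_null(rng):
    # identical groups: no stratification, hence no spurious structure
    spec = make_pair_spec("confounder2", prevalence=0.1, n=200_000,
                          fx=(0.2, 0.2), fz=(0.3, 0.3), group_prevalence_ratio=1.0)
    cohort = s.simulate(spec, rng)
    corr = m.stratified_correlation(cohort, "X", "Z")
    assert all(abs(v) < 0.02 for v in corr.values())
    est = m.odds_ratios(m.tabulate(cohort, ["X", "Z"]), min_cell=0)
    assert est.or_11 == pytest.approx(1.0, abs=0.1)


def test_confounder_ii_subsampling_leaves_or_unchanged(rng):
    spec = make_pair_spec("confounder2", prevalence=0.1, n=400_000,
                          fx=(0.10, 0.30), fz=(0.10, 0.35))
    cohort = s.simulate(spec, rng)
    full = m.odds_ratios(m.tabulate(cohort, ["X", "Z"]), min_cell=0)
    sub = m.odds_ratios(
        m.tabulate(s.subsample_case_control(cohort, rng), ["X", "Z"]), min_cell=0
    )
    assert sub.or_11 == pytest.approx(full.or_11, rel=0.2)


# ---------------------------------------------------------------------------
# Additive schemes
# ---------------------------------------------------------------------------

def test_additive_r_oracle_risk_ratios_exactly_additive():
    for cf in (0.01, 0.1, 0.3):
        spec = make_pair_spec("additive-r", prevalence=cf)
        est = m.relative_risks(amles.oracle_table(spec))
        assert est.reri == pytest.approx(0.0, abs=1e-12)


def test_additive_o_oracle_odds_ratios_exactly_additive():
    for cf in (0.01, 0.1, 0.5):
        spec = make_pair_spec("additive-o", prevalence=cf)
        est = m.odds_ratios(amles.oracle_table(spec), min_cell=0)
        assert est.amles == pytest.approx(0.0, abs=1e-12)


def test_additive_r_rejects_risk_above_one():
    spec = make_pair_spec("additive-r", prevalence=0.3,
                          fx=(0.05, 0.45), fz=(0.05, 0.45))
    with pytest.raises(ValueError, match="linear-risk"):
        s.simulate(spec, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Three-factor scenario
# ---------------------------------------------------------------------------

def test_three_factor_component_probabilities():
    # comp1's rate equals the either-of-comp2/comp3 rate; prevalence = p1^2
    probs = s._three_factor_probs(0.005)
    p1, q, q2 = probs
    assert q == q2
    assert 1 - (1 - q) ** 2 == pytest.approx(p1, rel=1e-12)
    assert p1 ** 2 == pytest.approx(0.005, rel=1e-12)


def test_three_factor_null_frequencies_give_unit_rrs(rng):
    factors = (s.FactorSpec("X", 0.2, 0.2, 0), s.FactorSpec("Z", 0.3, 0.3, 1),
               s.FactorSpec("V", 0.25, 0.25, 2))
    spec = s.ScenarioSpec(logic=s.Logic.THREE_FACTOR, factors=factors,
                          prevalence=0.01, n_components=3, n_individuals=200_000)
    table = m.tabulate(s.simulate(spec, rng))
    c = table.counts
    totals = c.sum(axis=-1)
    risk = c[..., 1] / totals
    rr = risk / risk[0, 0, 0]
    assert np.allclose(rr, 1.0, atol=0.35)
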