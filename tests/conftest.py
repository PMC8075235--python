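import numpy as np
import pytest

from amles import scenarios as s
from amles import metrics as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair_spec(logic, prevalence=0.005, n=100_000, *, fx=(0.15, 0.25),
                   fz=(0.10, 0.30), **kw):
    """Two-factor spec with fixed mid-range frequencies (no protocol draw)."""
    in_components = s.Logic(logic) in s.COMPONENT_LOGICS
    factors = (
        s.FactorSpec("X", fx[0], fx[1], 0 if in_components else None),
        s.FactorSpec("Z", fz[0], fz[1], 1 if in_components else None),
    )
    return s.ScenarioSpec(logic=s.Logic(logic), factors=factors,
                          prevalence=prevalence, n_individuals=n, **kw)


def oracle_agreement(spec, rng, n=100_000, n_se=4.0):
    """Simulated cell counts vs exact enumeration, within n_se binomial SEs.

    Returns (max_z, table) where max_z is the largest |observed - expected|
    in binomial-SE units over all factor-pattern x outcome cells.
    """
    probs, names = s.expected_cell_probabilities(spec)
    cohort = s.simulate(spec, rng)
    table = m.tabulate(cohort, names)
    obs = table.counts
    exp = probs * n
    se = np.sqrt(n * probs * (1.0 - probs))
    z = np.abs(obs - exp) / np.where(se > 0, se, 1.0)
    return float(z.max()), table
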