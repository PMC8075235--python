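# Methods

## The causal model

Every scenario describes a dichotomous outcome (case/control) produced by
latent binary *components* — causal sub-processes such as pathways. A
component is present in an individual with probability *p*, independently
of the other components. The observed risk factors are binary carrier
indicators coupled probabilistically to one component each: a factor is
drawn with its **high** frequency when the linked component is present and
its **low** frequency otherwise. Factors are therefore informative about,
but neither necessary nor sufficient for, the outcome — the dominant- or
recessive-model reading of a genetic risk allele.

Scenario logics: AND (all of *F* components required; synergism), OR (any
one suffices; heterogeneity of causes / phenocopying), THRESHOLD (at least
*t* of *F*; the multifactorial liability threshold), and the three-factor
structure comp1 AND (comp2 OR comp3). Two confounding schemes contain no
causal interaction at all: Confounder I draws cases and controls as
separate pools with different factor frequencies (the data-reuse artefact);
Confounder II mixes two subpopulations that differ in both frequencies and
prevalence (population stratification). Two further schemes are
purpose-built nulls: Additive-R assigns risk on a linear-probability scale
P(case|X,Z) = p0(1 + (rX−1)X + (rZ−1)Z), which makes risk ratios exactly
additive; Additive-O splits the population into two equal groups in which
only one of the two factors carries risk. A short derivation shows
Additive-O's expected odds ratios are *exactly* additive at every case
fraction: with u(z), v(x) the case/control frequency-ratio factors of the
two groups, every OR is of the form (u+v)/(u0+v0), and
OR10 + OR01 − 1 = OR11 follows by cancellation. Linkage disequilibrium
between factors is deliberately not modelled.

## Component probabilities and prevalence

Components are exchangeable: all share one probability *p* solved from the
target prevalence π (AND: p = π^{1/F}; OR: p = 1 − (1−π)^{1/F}; THRESHOLD:
P(Binomial(F,p) ≥ t) = π by bracketed root finding to |Δ| < 10⁻¹⁰). The
three-factor scenario follows its stated symmetry — components 2 and 3
share q, and component 1's rate equals their OR combination — giving
p1 = √π and q = 1 − √(1 − p1). The symmetric-probability reading of the
component/prevalence coupling is a design choice, not an asserted fact
about any external implementation; it is the minimal assumption consistent
with exchangeable components, and it reproduces the √f threshold law
exactly at the oracle level (below).

## Exact-allocation sampling

All simulators first fix the case count at round(n·π), then draw the
discrete cell states (component patterns, groups, or factor patterns)
*conditional on outcome* from the closed-form joint distribution, via one
multinomial per outcome class, before filling in factor values. This is
distributionally identical to forward simulation conditioned on the
realized case count, controls the case fraction to rounding error
(well inside the ±0.04% band used for the threshold experiments), and
costs ~50 ms per million-individual replicate. The same closed form is
exposed as `expected_cell_probabilities` — an exact enumeration oracle
summing over all 2^F latent states — and the test suite requires simulated
cell counts to match it within 4 binomial standard errors for every
scenario.

## Metrics

ORs are computed from the 2×2×2 table with the doubly-unexposed cell as
reference; RRs from outcome probabilities per exposure pattern. The
minimum-cell filter (≥ 5 in every cell) is the only guard against sparse
tables; no continuity correction is applied, and filtered replicates are
excluded from summaries with a machine-readable reason. AMLES is
(OR11 − (OR10+OR01−1)) / ((OR10−1)(OR01−1)); when the denominator is
within 10⁻⁹ of zero the estimate is undefined and reported as NaN. When a
single-factor OR is below 1 the scale's anchors invert; the value is still
reported, with a `ProtectiveFactorWarning`. f_est = sign(AMLES)·AMLES²,
f_thr = (t−1)/(F−1), RERI = RR11 − RR10 − RR01 + 1, and the interpolation
OR11 ≈ (1−√f)·additive + √f·multiplicative are direct formula
implementations. Pearson correlations between factors are reported for the
all/cases/controls strata, NaN when a stratum is degenerate.

## Experiments

`run_experiment` redraws factor frequencies per replicate (Z-like: low
uniform on [0.05, 0.15], multiplier uniform on [1.1, 4]; X-like:
[0.05, 0.25] × [1.1, 2]; high frequency clipped at 0.99 and flagged),
simulates a full cohort, computes RR metrics on it, and OR metrics plus
correlations on the analysis cohort — subsampled to equal cases/controls
when the case-control design is requested. Summaries are median, quartiles
and a percentile-bootstrap 95% CI of the median (1000 resamples of the
replicate vector), the statistics a notched boxplot shows. Randomness uses
one master seed with documented counter-derived substreams
(`SeedSequence([seed, tag, stream, grid_index, replicate])`), so any
replicate is reproducible in isolation. The default prevalence grid
{0.005, 0.02, 0.10, 0.33, 0.50} spans rare-disease to balanced designs;
correlation signs are reported with a ±0.01 dead band around zero.

Defaults are the study conditions: 10⁶ individuals per cohort and 1000
replicates. The experiments reported by `scripts/acceptance.py` and the
acceptance tests run at exactly these sizes (the threshold sweep at 500
replicates per t, and 100-replicate versions for the confounder and
three-factor checks, chosen so the whole suite completes in minutes while
keeping the medians' own sampling error a fraction of the tolerances).

### Small-sample behaviour of the AMLES estimator

AMLES is a ratio of correlated noisy quantities. When cell counts are
small (e.g. 500 cases from a 10⁵-individual cohort at 0.5% prevalence) or
the single-factor ORs are near 1 (the strongly diluted threshold scenario
at t = 1, where a case is usually caused by one of the other four
components), the per-replicate estimate is heavy-tailed and its median is
biased — at 10⁵ individuals the synergism median falls to ~0.7 and the
heterogeneity median to ~−0.6, recovering to 1.02 and ~0.0 at 10⁶. This
was verified against an independent pure-multinomial resampling check and
against the oracle, which shows the noise-free medians sit on the anchors
at both sizes; it is an estimator property, not a simulator artefact.
Consequently all headline experiments are run at the full 10⁶ size, and
the t = 1 point of the threshold sweep remains unresolvable at ±0.1 by any
feasible replicate count (its per-replicate 10–90% range spans roughly
−7 to +12). The noise-free medians over protocol frequency draws are
(0.005, 0.580, 0.780, 0.902, 1.011) for t = 1…5 with F = 5 — within 0.08
of √f_thr throughout, which is what "the square root of the threshold
fraction" means here in exact terms.

### Three-factor decomposition

The eight (XZ, XV, ZV) ∈ {add, mult}³ combinations are scored by composing
an expected RR111 from the single-factor RRs. The composition is
inclusion–exclusion: start from the fully additive RR100+RR010+RR001−2,
add the two-way excess (RRi−1)(RRj−1) for each pair labelled mult, and add
the three-way excess only when all three pairs are mult. This reproduces
the demonstrable anchor cases — all-mult = product, all-add = sum−2,
(mult,mult,add) = RR100·(RR010+RR001−1) — and yields eight distinct
formulas; it is a reconstruction, as the mixed-label cases are not defined
by any anchor. Combinations are ranked by |log(observed/expected)|.
Per-replicate ranking at 10⁶ individuals and 0.5% prevalence is noise-
dominated (the margin between the true combination and its nearest
competitor is 0.04–0.05 in log units against a joint-cell noise of ~0.13),
so the reliable statement is at the experiment level: the combination
whose per-replicate score is smallest at the median across replicates is
(mult, mult, add), the signature of X AND (Z OR V). Even noise-free, the
true combination wins only ~80% of frequency draws, because the
finite-prevalence correction (~1% at π = 0.005) can favour a neighbouring
formula when effects are weak.

## Randomizations and the scan

`rand1` permutes every factor column independently within cases and within
controls: per-status marginal counts are exactly preserved, within-status
dependence is destroyed, and the expected ORs of any pair become exactly
multiplicative — a positive control matching Confounder I. `rand2` splits
individuals 50/50 and resamples the anchor (group 1) or each test factor
(group 2) per-individual, with replacement, from the control-stratum
empirical values — an additive-OR control matching Additive-O. Whether the
resampling should be joint or per-individual is not externally fixed;
per-individual independent resampling is implemented. Status columns are
never modified. The pairwise scan reports the full effect-estimate row per
test factor against the anchor and keeps invalid rows flagged rather than
dropping them, so downstream counts remain auditable. The scheme is known
to moderate odds ratios somewhat; it is provided as the additive
counterpart, not as a calibrated null.

## Synthetic fixtures

`generate_fixture` builds multi-locus factor tables with known ground
truth, at case-control scale (default 20,000 individuals, 50% cases, 50
loci, X-like frequency protocol): `null` (no associations — AMLES mostly
undefined), `confounder1` (independent within status, higher frequencies
in cases — every pair exactly multiplicative in expectation), and
`additive-o` (shared two-group split — every anchor-locus pair exactly
additive in expectation). These emulate the *structure* of a real
case-control SNP table (an anchor such as a major HLA risk haplotype
versus many loci) but none of its genomic features: no linkage
disequilibrium, no allele-frequency spectrum, no covariates, no
genotyping error. Passing tests therefore validate the estimators and the
randomization machinery, not robustness to those real-data complications.

## Numerical choices and limitations

- Threshold root finding: Brent bracketing on [10⁻¹⁵, 1−10⁻¹⁵], xtol 10⁻¹⁴.
- AMLES undefined-denominator cutoff 10⁻⁹; undefined estimates are NaN and
  excluded listwise per metric.
- Bootstrap: percentile method, resampling replicates, not individuals.
- Ties in the three-factor ranking (all scores within 10⁻¹²) are reported
  as ties, with no best combination.
- Cohorts are written cases-first; row order is deterministic for a given
  seed, and identical spec + seed reproduces files byte-for-byte.
- The framework models dichotomous factors only; no quantitative traits,
  no covariate adjustment, no LD, and no genome-scale multiple-testing
  machinery.
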