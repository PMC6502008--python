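# Methods

## The estimand and the model

The package benchmarks knee-replacement *constructs* — a brand crossed
with fixation (cemented / uncemented / hybrid / monobloc), constraint
(unconstrained / posterior-stabilised / unicondylar) and bearing
mobility (fixed / mobile) — against the best-performing construct in the
same stratum, using registry time-to-event data.

Per construct and stratum, failure is summarised by **net failure**

    F(t) = 1 − Ŝ(t),

where Ŝ is the Kaplan–Meier product-limit estimator with revision as the
event and both death and the administrative extract date treated as
censoring.  Net failure estimates the revision-time distribution in a
hypothetical population without competing death; it is the right
quantity when the *risk* attributable to the implant is of interest, and
it is deliberately not the competing-risks cumulative incidence (which
answers a different question and is out of scope here).

The variance of F̂(t) is Greenwood's:

    Var(F̂(t)) = Ŝ(t)² · Σ_{tᵢ ≤ t} dᵢ / (nᵢ (nᵢ − dᵢ)),

with dᵢ revisions and nᵢ at risk just before event time tᵢ.  Greenwood
variance is computed on the plain survival scale (no log transform): the
resulting symmetric normal intervals are what the difference test below
assumes.

### The benchmark and the test

Within each (gender × age-band) stratum and at each evaluation time t ∈
{3, 5, 7, 10} years, the **benchmark** is the construct with the lowest
F̂(t) among those with at least 1000 procedures still at risk at t.  The
volume floor keeps the reference CI width near ±1.5%, tight enough to
act as a reference standard; ties on failure resolve to the larger
at-risk count, then lexicographic label, so selection is deterministic.

Every other construct x is compared with the benchmark through

    diff = F̂ₓ(t) − F̂_ref(t),
    se   = √(GSEₓ² + GSE_ref²),
    CI   = diff ± 1.959964 · se.

Two non-inferiority margins are carried, δ = 0.20·F̂_ref and δ =
1.00·F̂_ref (a 20% and a 100% relative increase in failure, converted to
the absolute difference scale).  Classification follows the CI rule:

| condition              | status                               |
|------------------------|--------------------------------------|
| CI upper ≤ δ₂₀         | non-inferior                         |
| CI lower > δ₁₀₀        | inferior by ≥100%                    |
| CI lower > δ₂₀         | inferior by ≥20%                     |
| otherwise              | inconclusive (non-inferiority not shown) |

The reported p-value is the one-sided upper-tail normal probability of
|diff|/se — the convention the published comparison tables follow (their
zero-difference row prints p ≈ 0.5, and their p-values reproduce from
|diff|/se rather than from the margin-shifted statistic).  The
margin-shifted statistic zₙᵢ = (diff − δ₂₀)/se and its tail probability
are reported separately; a configuration switch reproduces the additive
sign convention (diff + δ)/se used in some historical output.  The CI
rule, which drives all classification, is unaffected by that sign
choice.

A reference failure of exactly zero collapses both relative margins to
zero; the comparison is flagged `margin_undefined` rather than refused.

### Reporting thresholds

Comparators need ≥250 procedures at risk to enter tabular output and
≥500 to enter graphical summaries and the headline counts.  The
benchmark construct counts toward "constructs in use at the threshold"
but never toward a status tally, so status counts sum to the construct
count minus one.  Inferior-by-≥100% is always counted inside
inferior-by-≥20%.

### Stratification

Strata are all procedures, each gender, and gender × age band with bands
<55, 55–75, >75 read literally: [0, 55), [55, 75], (75, ∞), so both
boundary ages fall in the middle band.  Ages are banded as exact
decimals by default; an `integer_ages` switch truncates to completed
years first.  Strata are analysed independently — no pooling or
shrinkage across cells.  A stratum with no eligible benchmark is
reported as unanalysable, with zero comparisons.

### Sensitivity analysis

`run_sensitivity` selects the benchmark once per stratum at a late
anchor time (10 years by default, ≥1000 at risk there) and uses that
construct as the reference at every earlier configured timepoint.
Comparing against the contemporary analysis separates genuine construct
inferiority from temporal improvement of the benchmark itself.

## Numerical conventions

- **Ties**: revisions are processed before censorings at equal times
  (the standard product-limit convention), so a procedure censored at an
  event time is still in that event's risk set.
- **At-risk counting** uses observed time ≥ t (boundary included): a
  procedure revised exactly at t is at risk at the start of t.
- **Zero follow-up** (same-day revision) is shifted to one day
  (1/365.25 years) so every event time is strictly positive.
- **Exhausted risk sets**: if some nᵢ = dᵢ, failure is exactly 1 from
  that time on and the Greenwood sum truncates at the last term with
  nᵢ > dᵢ, keeping the SE finite.
- **Evaluation beyond follow-up** returns the last observed value with
  an `extrapolated` flag; the curve is never extended.
- **Scales**: failures are proportions internally; percent rendering (2
  decimals, p-values to 3 with a `<0.001` floor, decimal point, no
  thousands separators) happens only in the report writer.
- Exclusion precedence is fixed (missing demographics → untraceable →
  unknown fixation/constraint → patellofemoral), each record counted
  once under the first applicable reason, so the exclusion log always
  sums to the number removed.

## The synthetic registry

`scenario_like_paper()` bundles the default study conditions: ~20
total-knee constructs with true 5-year failures 1.2–5%, six unicondylar
constructs with 4.2–12%, one dominant low-failure construct (32 000
procedures) intended as the benchmark, uniform accrual April 2003 to
end-2016, administrative censoring at end-2016, 43% male, ages
truncated-normal(70, 9) on [20, 100].  The failure ranges echo the
magnitudes national registries report at five years; the dominant
construct's volume mirrors the 10–100× volume advantage real benchmark
constructs enjoy.

Revision times are piecewise-exponential per construct (constant rates
in the bundled scenario); death times are exponential with hazard
0.02·exp(0.09·(age − 70)) per year — a log-linear age effect chosen to
create realistic age-dependent censoring pressure (roughly doubling
every 8 years of age) without a full life table.  Observed time is the
minimum of revision, death and the administrative horizon, rounded to
the day grid, with ties resolved revision > death > administrative.
Because death is generated independently of revision given age, 1-KM on
simulated data is a consistent estimator of the latent revision-time
CDF, which the tests exploit as a closed-form oracle.

What the generator does **not** emulate: confounding by indication
(unicondylar implants chosen for younger, fitter patients), surgeon and
unit effects, brand-specific age targeting, bilateral-procedure
clustering within patients, and calendar drift in revision thresholds.
Passing tests therefore demonstrate the statistical machinery is
correct under the stated sampling model, not that registry estimates
are free of selection effects.

## Calibration experiments and their regimes

- **CI coverage**: 95% normal intervals F̂ ± 1.96·GSE cover the true
  exponential failure at 5 years in ≈95% of 2000 replicates of n = 1000
  with staggered-entry administrative censoring (tolerance ±1.5
  percentage points).
- **Boundary type-I error**: with the comparator's true failure exactly
  at the 20% margin (1.2 × reference), the one-sided 2.5% test declares
  non-inferiority in ≈2.5% of 2000 replicates (comparator n = 1000,
  reference n = 20 000, tolerance ±1 point).  This calibration is run at
  a reference failure of 0.25, i.e. ~300 comparator events, the regime
  where the Wald-type test's normal approximation is accurate.  **Known
  limitation**: below roughly 100 events the test is anti-conservative —
  exact binomial computation puts its one-sided size at 3.2–5.4% for
  failure probabilities of 2–6% at n = 1000 — because the estimated
  Greenwood SE shrinks exactly when the estimate strays low.  Low-volume
  comparisons near the margin should therefore be read as slightly
  liberal; the classification of strong signals is unaffected.
- **Classification consistency**: the pipeline on the bundled scenario
  recovers each construct's true 5-year failure within 3 SEs and labels
  every high-volume construct with true failure ≥3× the benchmark as
  inferior by ≥100%.  The ≥3× cut, rather than the asymptotic >2×,
  reflects desk-scale volumes: a construct at ~2.6× the benchmark with
  ~1500 at risk sits within one SE of the doubling margin and
  legitimately classifies as inferior-by-≥20% — exactly the borderline
  behaviour visible in published tables.

## Design choices that were genuinely open

- Whether the Greenwood variance should be computed via a log
  transform: plain scale was chosen because the published symmetric CIs
  are consistent with untransformed normal intervals.
- The sign of δ in the auxiliary z statistic (the subtractive standard
  form is the default; the additive form is available), and the scale of
  δ (proportion internally; classification by CI is scale-consistent
  either way).
- Benchmark tie-breaking (larger at-risk, then label) — any
  deterministic rule works; this one prefers the tighter reference.
- Exclusion precedence order — aggregate counts are insensitive to it;
  fixing it makes the per-reason log reproducible.
- The reference arm size in the type-I experiment (20×the comparator):
  with equal arms, noise in the estimated margin alone inflates the
  one-sided rate by a further ~1 point, a property of equal-arm designs
  rather than of the method as used, since real benchmarks dominate
  their strata.

## Problem sizes

The bundled scenario simulates ~107 000 procedures across 26 constructs
and runs the full stratified analysis in a few seconds; the calibration
suites use 2000 replicates each (n = 1000–21 000 per replicate) and 1000
exhaustive small instances for the product-limit oracle, keeping the
whole test suite within a few minutes on one CPU.
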