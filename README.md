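# kneebench

Non-inferiority benchmarking of knee-replacement constructs from
registry time-to-event data.

National arthroplasty registries publish absolute revision rates for the
most common knee implants, but absolute rates do not answer the question
a patient or surgeon actually has: *is this construct demonstrably no
worse than the best one available for someone like me?*  `kneebench`
implements a head-to-head benchmarking analysis that answers it.  It is
written for registry analysts and outcomes researchers working with
procedure-level extracts (one row per primary knee replacement with
construct identity, demographics and follow-up outcome), and ships a
synthetic registry generator so the whole pipeline is testable without
access to confidential registry data.

## The method

For each *construct* (brand × fixation × constraint × bearing, total or
unicondylar) within a stratum (gender, age band) the package estimates
**net failure** by 1 − Kaplan–Meier, with revision as the event and
death / end-of-study as censoring, and Greenwood standard errors:

    F̂(t) = 1 − ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ),
    GSE(t) = Ŝ(t) √( Σ_{tᵢ ≤ t} dᵢ / (nᵢ(nᵢ − dᵢ)) ).

The **benchmark** is the construct with the lowest F̂(t) among those with
≥1000 procedures still at risk at t.  Every other construct is tested
against it through the difference diff = F̂ₓ − F̂_ref with pooled SE
√(GSEₓ² + GSE_ref²) and a 95% CI, against non-inferiority margins
δ = 0.2·F̂_ref and δ = 1.0·F̂_ref:

- CI upper ≤ δ₂₀ → **non-inferior**;
- CI lower > δ₁₀₀ → **inferior by ≥100%** (at least doubled failure);
- CI lower > δ₂₀ → **inferior by ≥20%**;
- otherwise → **non-inferiority not shown**.

Analyses run at 3, 5, 7 and 10 years, overall, by gender, and by gender
× age band (<55, 55–75, >75), with reporting floors of 250 (tables) and
500 (figures and headline counts) procedures at risk.  A sensitivity
mode re-runs earlier timepoints against the construct that is best at 10
years, separating construct inferiority from temporal improvement of the
benchmark.  See `docs/methods.md` for conventions and calibration.

## Worked example

Simulate a registry-shaped dataset (26 constructs, ~107 000 procedures,
accrual 2003–2016) and run the full stratified analysis:

```sh
kneebench simulate --seed 1 --out registry.csv
kneebench analyze registry.csv --outdir reports/
```

which prints, among the 36 stratum × timepoint cells:

```text
report_all_all_5y.csv: 23 constructs at figure threshold, 18 inferior >=20% (8 >=100%), 0 non-inferior, 4 inconclusive
```

i.e. at 5 years, 23 constructs had ≥500 procedures at risk; 18 of the 22
comparators were inferior to the benchmark by at least a 20% relative
increase in failure, 8 of those by at least 100%.  The per-cell CSV
mirrors a published benchmarking table (reference row first):

```text
                                 construct_label  n_at_risk  cumulative_failure_pct  difference_pct  ci_low_pct  ci_high_pct        equivalence_status p_value
       (TKR) Atlas cemented, unconstrained fixed      17718                    1.21                                                        (Reference)
(TKR) Atlas cemented, posterior-stabilised fixed       3268                    2.22            1.01        0.55         1.46         Inferior by >=20%  <0.001
     (TKR) Atlas uncemented, unconstrained fixed       1366                    2.25            1.03        0.33         1.73         Inferior by >=20%   0.002
    (TKR) Borealis cemented, unconstrained fixed       4974                    1.61            0.40        0.07         0.73 Non-inferiority not shown   0.008
```

The generator's true 5-year failure for the benchmark construct is 1.2%
(estimated 1.21% with 17 718 at risk); the posterior-stabilised variant
(true 2.2%) is correctly flagged as inferior by ≥20% but not by ≥100%.

The same analysis is available as a library — an sklearn-style estimator
that composes with sklearn tooling:

```python
from kneebench import StratifiedBenchmarkAnalysis, apply_exclusions
from kneebench.io import read_procedures

records, log = apply_exclusions(read_procedures("registry.csv"))
model = StratifiedBenchmarkAnalysis(timepoints=(5.0,)).fit(records)
tidy = model.transform()          # one row per construct comparison
```

Two published gender-specific 5-year comparison tables ship as fixtures
(`kneebench.tables`); `kneebench verify-tables` re-derives every
difference and equivalence status in them from the printed failures and
CIs and exits non-zero on any mismatch.

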