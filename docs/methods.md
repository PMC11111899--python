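# Methods

## Scope and data model

`pvsignal` implements a pharmacovigilance analysis of spontaneous
adverse-event reports in the structure used by the FDA Adverse Event
Reporting System (FAERS): quarterly `$`-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, THER) keyed by `primaryid = caseid*10 + caseversion`.  Adverse
events are MedDRA-style preferred terms (PTs), each belonging to one system
organ class (SOC).  Because MedDRA is licensed and no public accession
accompanies the analysis this package was built around, every stage runs
against a synthetic generator that reproduces the *structure* of the data —
versions and duplicates, role codes, multiple PTs per case, demographic
missingness, partial dates — with known planted ground truth.

## Deduplication

FAERS re-publishes cases as new versions.  One report per case is kept: the
highest `caseversion`, ties broken by latest receipt date (`fda_dt`), then
largest `primaryid`; verbatim row copies are collapsed first.  The rule is
deterministic (output sorted by case id) and idempotent.  Missing receipt
dates sort earliest, so a dated re-submission always beats an undated one.

## Counting unit and contingency tables

The counting unit is the unique (case, PT) pair after deduplication;
"exposed" means the case lists the target drug with role PS (primary
suspect), matched by whole-name equality against a configurable list of
name variants (trim + case-fold; no substring matching, so salt forms do
not match the plain name).  For a target drug and PT, the universe of units
partitions into the 2x2 table (a, b, c, d) with N = a+b+c+d.  SOC-level
tables collapse the unit to (case, SOC); by default a case with several PTs
in one SOC counts once there (`dedup_within_case=False` switches to summed
PT units).

## The four statistics

With SE = sqrt(1/a + 1/b + 1/c + 1/d) and z = 1.96 (used exactly as the
conventional printed constant, not the 1.95996 quantile):

* ROR = ad/bc, CI = exp(ln ROR ± z·SE).  Signal: a ≥ 3 and lower CI > 1.
* PRR = [a/(a+b)] / [c/(c+d)]; Pearson chi-squared without continuity
  correction.  Signal: a ≥ 3, PRR ≥ 2, chi² ≥ 4.
* EBGM = aN/[(a+b)(a+c)], the closed-form relative reporting ratio used as
  the MGPS point estimate (no empirical-Bayes gamma-mixture fit is
  attempted); EBGM05 = exp(ln EBGM − z·SE).  Signal: EBGM05 > 2.
* BCPNN IC = log₂(aN/[(a+b)(a+c)]), with conjugate-prior posterior moments
  E(IC), V(IC) (hyperparameters α₁=β₁=1, α=β=2, γ₁₁=1, γ derived) and the
  lower bound IC−2SD = E(IC) − 2·sqrt(V(IC)).  Signal: IC−2SD > 0.

Two naming quirks are deliberate: the column usually labelled "IC025" is
exactly the IC−2SD bound above, and "EBGM05" uses the two-sided 1.96 bound —
in both cases the formula, not the label, is authoritative here.  Under
these closed forms EBGM = 2^IC identically; the test suite asserts the
identity to 1e−12 relative tolerance.

A *consensus signal* requires all four criteria simultaneously.  An
undefined statistic (zero margin) can never vote: its flag is false.

**Zero-cell policy.** If any of b, c, d is zero, ROR and its CI use the
Haldane–Anscombe +0.5 on all four cells; PRR, EBGM and IC use raw cells and
return NaN on zero denominators.  The a ≥ 3 gates dominate real decisions,
so the correction affects only reported magnitudes of non-signals.

**Monotonicity.** ROR and PRR are strictly increasing in a with b, c, d
fixed.  EBGM and IC are strictly increasing only where bc > a², because N
grows with a; outside that regime (a comparable to the margins) they can
decrease.  The property test asserts monotonicity on the
disproportionality-relevant regime (a far below both margins).

## Date policy

Dates are day-precision YYYYMMDD.  Month-precision values (YYYYMM) occur in
real extracts and in the generator (5% of date fields); they are kept as
text for provenance but treated as missing for all arithmetic — fabricating
a day would bias onset intervals.  Onset = event date − earliest therapy
start of the target PS drug; negative or incomputable onsets are excluded
from the onset denominator.

## Subgroup analysis

Within the target drug's deduplicated reports, cases are reports carrying a
configurable outcome PT set; the exposure is sex.  Model I is the 2x2
cross-product OR with Wald CI (Haldane on zero cells, flagged).  Model II
is a maximum-likelihood logistic fit (statsmodels Newton, tol 1e−10) with
age and weight continuous, reporter and outcome code categorical with the
largest class as reference, complete-case.  With a single binary predictor
the MLE equals the closed-form OR to 1e−6 relative — the equivalence test.
Perfect separation (including a constant outcome) raises an error instead
of emitting an estimate.  Age bins are <18, 18–64, 65–85 (inclusive at both
ends), >85 strictly greater; demographic percentages use the full case
count as denominator and are reported to one decimal.

## Network pharmacology

The module consumes exported tables, never live databases: scored gene
tables (filtered at their documented cutoffs, duplicate symbols resolved by
maximum score), an edge TSV (optionally confidence-filtered at
combined_score ≥ 0.7 while loading), and GMT annotation sets.  Symbols are
normalised by trim + upper-case only; no alias resolution.  Degree is
incident-edge count on the simple graph (self-loops dropped, duplicate
edges collapsed); core genes have degree strictly greater than the cutoff
(default 10 — the cutoff is a parameter because "top-hub" conventions
vary).  Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with Benjamini–Hochberg adjustment, run within each declared
namespace (GO-style practice) or globally; significance is adjusted
p < 0.05.

## The synthetic generator

Each case gets one uniformly drawn PS drug plus Poisson(0.8) concomitant
drugs; background PTs arrive as a truncated-geometric count (mean 3,
capped at 10, configurable) drawn from the non-planted PT pool, so a case
always has at least one reaction.  A planted signal (drug d, PT p, r ≥ 1)
makes p an independent Bernoulli event: probability b (the
`baseline_event_rate`) for every case and min(1, r·b) when the PS drug is
d, so the per-case exposed/unexposed reporting-rate ratio is exactly r.  A
`duplicate_fraction` of cases is re-submitted (version 2, receipt 7–90 days
later) and a tenth of that rate appears as verbatim row copies; 5% of date
fields are month-precision; demographics go missing independently at the
configured rate.

What the generator does **not** emulate: correlated reporting (PT
co-occurrence syndromes), drug–drug confounding, secular reporting trends,
reporter-dependent coding quality, masking by large signal drugs, and
narrative text.  Passing recovery tests therefore show the *estimators and
thresholds* behave as designed under clean disproportionate reporting, not
that real-data confounding is handled.

## Validation study design

The recovery study plants r ∈ {1, 5, 10} on distinct (drug, PT) pairs in
quarters of 20,000 cases, n_drugs = 60, baseline b = 0.1, and repeats over
20 seeds, with 20 matched null quarters.  The design was fixed by a power
analysis before any test was run: r = 1 needs the expected exposed event
count m·b ≳ 40 (m = exposed cases) for a stable ratio, while r = 10 needs
both a small exposed fraction and r·b ≤ 1 — the EBGM for a planted pair is
deflated by the factor (μ+b)/(μ+rb) · 1/(1+f(r−1)) (μ = mean background
multiplicity, f = exposed pair share) because the planted events inflate
the exposed margin.  b = 0.1 with m ≈ 333 satisfies both (predicted EBGM ≈
6.9 at r = 10, observed 6.8).  At the example baseline b = 0.01 the ±35%
recovery band is unattainable for r = 1 and r = 10 simultaneously at any
drug count; this is a property of pair-unit disproportionality estimators,
not of the implementation.

Under the null, the grand mean of IC and ln ROR across observed pairs
carries the systematic Jensen bias of log ratios, about −1/(2·E[a]) on the
ln scale (measured −0.0025 at E[a] ≈ 220) — far larger than the tiny
across-seed standard error, because margins are shared.  The null test
therefore asserts the meaningful calibration statement: the bias is within
3× the mean per-pair standard error, i.e. negligible on the scale of any
single pair's uncertainty.

## Problem sizes and numerics

Unit tests run on 1,500–2,000-case quarters; the recovery and null studies
use 20 seeds × 20,000 cases (about 15 s total); the logistic recovery uses
20 cohorts of 5,000.  The acceptance script re-runs the recovery study and
the fixture-based network analysis from scratch at those sizes.  All
randomness flows through `numpy.random.default_rng` seeds carried in the
configurations; identical configuration ⇒ byte-identical outputs.  The
gene fixture realises its degree sequence with Havel–Hakimi, so "exactly
11 nodes above degree 10 with 198 edges over 76 nodes" is a constructed,
not sampled, property.

## Known limitations

* EBGM here is the closed-form observed/expected ratio, not a fitted
  gamma-Poisson shrinker; small-count pairs are therefore less shrunk than
  a full MGPS would produce.
* The published per-PT signal tables cannot be reproduced row-by-row: the
  marginal counts b, c, d behind them are not public, and reconstruction
  from the printed statistics is over-determined and inconsistent at
  printed precision.  The package instead verifies internal identities
  (e.g. IC = log₂ EBGM) and end-to-end recovery on planted ground truth.
* The adjusted (Model II) coefficients of the original cohort are likewise
  not reproducible without individual-level covariates; the package
  specifies the fitting contract and demonstrates parameter recovery on
  synthetic cohorts.
* Country names and drug names pass through verbatim; no RxNorm/ATC or
  gene-alias mapping.
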