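# Methods

## Scope and model

`trialcea` implements a trial-based economic evaluation of a two-arm
intervention from a health-service-provider perspective. The estimand chain
is: resource-use counts → annual per-participant costs per scenario;
questionnaire outcomes → two endpoints (post-intervention PHQ-9 and a
12-month QALY); covariate-adjusted arm differences in costs and effects;
and decision-analytic summaries (bootstrapped ICERs, NMB regressions,
CEACs). Only direct healthcare costs are modelled; there is no discounting
(one-year horizon) and no indirect-cost component.

## Costing

**Resource use.** Nine service categories (GP, other outpatient
specialist, emergency, mental-health specialist, remedies/other therapists,
counselling/support, pharmacy visits, inpatient general days, inpatient
psychiatric days) are recorded as contacts/days per 13-week recall window
at each occasion. Costs are counts × unit costs. Unit costs are
configuration (YAML), shipped with illustrative 2019 euro defaults; prices
can be moved between years with a consumer-price-index series
(`index_price`, ratio of CPI values).

**Annualization.** The follow-up annual cost is the sum of the
post-baseline windows rescaled to 52 weeks by the covered-weeks ratio
(three 13-week windows → factor 52/39); the baseline window is annualized
separately (× 52/13) and serves only as a covariate. An alternative rule
(mean window × 4) is available; the two coincide for 13-week windows.
Pharmacy visits are costed at a flat per-visit rate — medication prices are
not recoverable from visit counts.

**Programme micro-costing.** Annual personnel, operating and consumables
expenses divided by a participant denominator: the intention-to-treat count
(`basis="itt"`) or full capacity, groups/year × group size
(`basis="optimal"`). The ledger carries optional full-capacity expense
overrides because an optimally utilised programme has a different expense
profile than the trial roll-out; with a single expense total the two
published per-capita figures (409.6 and 347.9 euros) would be mutually
inconsistent. The bundled default ledger is a **synthetic reconstruction**:
the component split is invented and only the totals are anchored so the two
per-capita figures and the 128-participant capacity (16 × 8) reproduce.

**Scenarios.** base = resource cost + ITT programme cost (intervention arm
only); on_top = programme cost only (control total 0); optimal = resource
cost + full-capacity programme cost. Internal arithmetic is unrounded;
currency is rounded to 0.1 euro only at report time.

## Outcomes

**LOCF.** Missingness is assumed monotone (dropout); each missing cell is
replaced by the participant's last observed value of that variable.
Everyone must be observed at baseline. The operation is idempotent and
leaves observed cells untouched. LOCF is conservative: under dropout it
pulls arm differences toward zero, which is also why the generator's ground
truth is stated for complete data.

**Utilities and QALYs.** WHOQOL-BREF items (26, 1–5 Likert) are scored to
the four standard domains — reverse-scoring items 3, 4 and 26, domain mean
× 4, linear map to 0–100 (items 1–2 enter no domain). The domain-to-utility
conversion is a pluggable strategy; the default is the equal-weight linear
stand-in (mean of the four domains / 100), monotone non-decreasing in every
domain. The published conversion algorithm's coefficients are not public,
and inventing them would fabricate a value set; any monotone mapping can be
injected via `utility_map`. The 12-month QALY is the area under the utility
trajectory (trapezoid between occasions, the week-48 value carried flat to
week 52) divided by 52; a step (piecewise-constant) interpolation is
offered as an option since the published description does not fix the rule.

**Adjusted effects.** OLS of the endpoint on an intervention indicator,
age, gender, site (fixed categorical effects) and the baseline endpoint,
with HC3 robust standard errors (the estimator behind the published
adjusted differences is not named; OLS + robust SEs is the conservative
default). PHQ-9 effects are also exposed sign-flipped to a reduction scale
so that positive = improvement, which keeps "south-east = dominance" on the
CE plane. Singular designs raise rather than silently dropping terms.

## Cost regression

Gamma GLM with **identity link on log(cost + 1)**, covariates arm, age,
gender, site and log(baseline cost + 1); the arm coefficient is
exponentiated to a ratio with the exponential of its CI. This response/link
combination is unusual but implemented literally as described for the
analysis being reproduced; a conventional alternative (gamma, log link, on
cost + 1) is available via `model="gamma_log"`. The +1 offset handles
zero-cost windows; a participant with exactly zero annual cost makes the
gamma response non-positive and raises a `DegenerateDataError` (the
Table-1 builder catches it per category and reports NaN). The ratio is
invariant to common cost rescaling only up to the offset's influence, which
vanishes at costs well above 1 euro.

## Bootstrap, NMB and CEAC

**Bootstrap protocol.** One `numpy.random.default_rng(seed)`; per replicate
the intervention indices are drawn first, then control, each uniformly with
replacement preserving arm sizes; ΔC and ΔE are re-estimated by OLS per
replicate (refitting unifies the "bootstrapped" and "adjusted" quantities).
A single covariate set — age, gender, site, baseline cost, baseline
endpoint — is used for the cost, effect and NMB regressions, making the
INMB x-intercept identity exact: INMB(λ) = λ·ΔE_adj − ΔC_adj, root =
adjusted ICER. Per-replicate fits use normal-equation solves with a
minimum-norm least-squares fallback for singular replicates (a site level
can vanish under resampling); this matches a naive OLS loop
replicate-for-replicate.

**ICER summaries.** Percentile (2.5/97.5) bootstrap intervals; no BCa.
Replicates with |ΔE| ≤ 1e-10 are excluded from the ICER mean/percentiles
with a logged count — the ratio is unstable near ΔE = 0 — but still count
toward quadrant shares (ΔC ≤ 0 counts as south, ΔE ≤ 0 as west, so shares
always sum to 1).

**Acceptance probability.** P(INMB > 0) from the arm coefficient's t
sampling distribution with classical OLS standard errors. Classical (not
robust) SEs are used here deliberately: they make the CEAC's large-λ limit
equal the effect-only regression's one-sided probability exactly. CEAC
thresholds (`threshold_confident`: smallest λ with CI low ≥ 0;
`threshold_minimum`: CI high ≥ 0) are linearly interpolated between grid
points. Default λ grids: 0–2000 euros step 10 per PHQ-9 point; 0–100 000
euros step 250 per QALY.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes: arms of
81/68 participants across 7 sites; occasions at weeks 0/12/24/48 with
13-week recall; baseline PHQ-9 drawn inside the 15–19 inclusion window
(mean 17); post-occasion PHQ-9 = baseline + 0.7 drift + arm effect (default
−2.0 points) + N(0, 4) noise, rounded and clipped to 0–27; a latent
quality-of-life level (baseline N(0.45, 0.12)) shifted by +0.04 in the
intervention arm from week 12 and measured through the 26 items (item =
round(1 + 4q + N(0, 0.55)) clipped to 1–5, reverse items stored reversed);
per-category per-window costs as Bernoulli(0.5) × Gamma(0.8, scale) contact
intensities × unit cost, with multiplicative site factors (0.7–1.3, mean 1)
and arm-specific scales chosen so the annualized resource-use means are
1401.1 (intervention) and 2231.8 (control) euros/year with a mental-health
share of ~15% vs ~40%; gender 61.7% male, age N(32.2, 9.4) clipped 18–65;
monotone dropout at 0.1 per occasion. "Counts" are continuous intensities
(fractional contacts), which keeps the gamma mean identity — expected
window cost = p·k·θ·unit — exact for `ground_truth`.

What it does **not** emulate: intermittent missingness, informative
dropout, baseline-vs-follow-up cost level differences, correlation between
cost categories or between costs and outcomes, integer contact counts,
heavy inpatient zero-inflation beyond the single Bernoulli gate, and any
site-by-arm interaction. Passing recovery tests therefore show the
estimators are correct under these idealised conditions, not that real
trial data meet them.

`ground_truth` returns complete-data expectations (annual cost by arm via
the gamma mean identity and the mean site multiplier; ΔE on both the native
and reduction scales; the QALY difference as the trapezoid weight 46/52 of
a constant post-baseline utility shift). Under dropout > 0, LOCF attenuates
arm effects relative to these values, so recovery tests run at zero
dropout.

## Numerical choices and degenerate inputs

Fixed draw order in the generator gives bit-identical datasets per seed.
All randomness flows through explicit integer seeds recorded in outputs;
the pipeline manifest (versions, seed, config hash) reproduces every number
byte-identically. Validation errors are raised for: probabilities outside
[0, 1], non-positive gamma shapes/scales, baseline PHQ-9 means outside the
inclusion window, non-monotone missingness, missing baseline observations,
out-of-range questionnaire items, unknown categories/scenarios/endpoints,
empty λ grids, zero programme-cost denominators and missing CPI years.

## Problem sizes used in validation

The test suite exercises: convergence of simulated means to ground truth at
2000 participants per arm (5% tolerance); CI coverage of an injected −2.0
PHQ-9 shift at 500 per arm over 100 seeds; bootstrap recovery of injected
ΔC = −800 euros and ΔE = +2 reductions at 81/68 over 50 seeds with 1000
replicates (3 Monte-Carlo-SE criterion); null calibration (CEAC acceptance
≈ 0.5, gamma-GLM ratio coverage ≥ 90%) over 100 seeds; and
replicate-for-replicate equivalence of the bootstrap engine with a naive
OLS loop on a 20-participant fixture at 200 replicates. The acceptance
script runs the default 149-participant conditions with 10 000 replicates.

## Known limitations

The default utility mapping is a stand-in, not a published value set, so
QALY levels are not comparable across studies. The gamma-identity-on-log
cost model is reproduced as described but is not the conventional
health-econometrics specification; use the `gamma_log` alternative for
sensitivity. LOCF is a single-imputation method that understates
uncertainty. The unit-cost defaults are illustrative, and the programme
ledger's component split is synthetic. ICER confidence intervals are
percentile bootstrap only (no Fieller or BCa), and the bootstrap refits a
correctly-specified OLS — model misspecification is not propagated.
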