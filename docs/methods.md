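# Methods

This note records the model as implemented, the parameter choices that were
genuinely open, and what the tests do and do not establish.

## Natural history

Women are simulated independently.  Other-cause mortality comes from a
2-column life table (age, annual hazard); the shipped fixture is a synthetic
Gompertz–Makeham curve, h(a) = 3·10⁻⁴ + 1.2·10⁻⁵·e^{0.105a}, chosen to give
a cohort life expectancy near 80 years (a US-1970-like female cohort).  It is
a stand-in, not a national life table; any table can be supplied as CSV.

With probability `lifetime_bc_risk` a woman develops one tumor (second
primaries are out of scope).  Invasive tumors grow exponentially in diameter
from 0.01 cm at onset; exponential growth is the standard companion of the
fatal-diameter cure mechanism and has a closed-form inverse, which the
simulator uses throughout (all crossing times are computed analytically — no
time stepping).

Cure is purely mechanical: diagnosis strictly before the fatal-diameter
crossing ⇒ death by other causes; at or after ⇒ breast-cancer death at
(crossing time + sampled survival), censored by other-cause death.
Treatment enters only through stage-specific costs and utilities; every
diagnosed woman is treated.

A tumor that crosses d_fatal can kill before it would have surfaced
clinically (about a tenth of breast-cancer deaths at the defaults die
undiagnosed).  Such women receive no care costs or decrements in the
control universe; this slightly understates control-arm costs and is
accepted as a desk-scale simplification.

DCIS is a pre-invasive state with an exponential dwell and a categorical
fate: regress (never surfaces), progress (the invasive growth clock starts
at the end of the dwell), or surface as clinical DCIS.  Screen-detected or
clinically surfacing DCIS is staged in situ and never fatal; a progressing
DCIS missed during its dwell is simply an invasive cancer afterwards.

Stage at diagnosis is assigned from diameter with half-open, lower-inclusive
T-size breakpoints (default 2 cm and 5 cm; configurable): in situ for DCIS,
then local / regional / distant.  This is artifact plumbing — the cost and
utility tables are keyed by stage — not a clinical staging model.

## Screening

A policy is an arithmetic schedule (default 50, 52, …, 74) with an
attendance probability (default 1.0).  At each attended screen before any
diagnosis and before death:

* an invasive tumor is detected iff its diameter has reached its personal
  d_screen, drawn from a Weibull whose median is the test's median detection
  size (shape default 2.0, configurable; the spread it controls is not
  identified by any calibration target here);
* pre-clinical DCIS is detected with the test's DCIS sensitivity,
  independently per round;
* otherwise the screen is negative and contributes (1 − specificity)
  *expected* false positives.

False positives are deterministic expected weights by default, with a
Bernoulli mode for uncertainty work.  The published quantities are per-1000
expectations (the biopsy share of false positives is likewise applied in
expectation), and the expectation mode makes the structural identities exact
rather than asymptotic: the false-positive count is exactly affine in
(1 − specificity), and QALYs and the maximum price are exactly monotone in
specificity.

Each tumor carries one detectability *quantile*, mapped through each
scenario's Weibull inverse CDF.  One draw per tumor honours the
"unique size per tumor" reading while keeping detectability comonotone
across scenarios, so combined sensitivity is exactly monotone in the median
detection size at fixed seed.

All natural-history randomness lives in named substreams separate from the
screening streams, and all scenarios in a run share both the cohort and the
screening streams (common random numbers): two scenarios differ only through
their test characteristics.  Women exit screening permanently at diagnosis;
false positives do not alter the schedule.  Test performance is
age-constant.

Detection counting uses the diagnosis-age window [50, 75) and partitions
diagnoses into screen-detected vs clinically/interval-detected, by pathology
(invasive vs DCIS); the three reported sensitivities are the screen-detected
shares, rounded half-up to integer percent.

## Outcomes and economics

Life-years run from age 30 to death, discounted at 3%/year to age 30
(continuous accrual; the discount anchor is a package choice — only the rate
is externally fixed).  QALY decrements are additive, (1 − utility) ×
duration: point-discounted at the event age for short events (screen:
utility 0.994 for 1 week; true-positive, clinical and false-positive
work-up: 0.895 for 5 weeks), continuously accrued for care phases.  Care
phases partition diagnosis-to-death exactly: initial = first 12 months,
terminal (or terminal-OCD for other-cause decedents with a breast-cancer
history) = last 12 months, continuous = the remainder; for survivals under
two years the later phases truncate.  Overlapping screening/work-up and care
decrements in the same period are summed, not compounded; the resulting
double count is negligible at these utility levels.

Costs mirror the same ledger in 2020 USD: per-screen price, false-positive
imaging for every FP plus biopsy for 10.6% (in expectation), diagnostics at
diagnosis by age band, and stage×phase care costs (initial and terminal as
lump sums at phase start, continuous accrued per year).  Initial and
terminal lump sums are charged in full for every diagnosed decedent, even
when the survival span is shorter than the nominal phase; this overstates
costs for the small group diagnosed under a year before death.

Overdiagnosis requires the control universe to show *neither* a clinical
diagnosis *nor* a breast-cancer death: a screen detection of a cancer that
would have killed undiagnosed is a late true positive, not an overdiagnosis.

ICERs are ΔC/ΔQ against the digital-mammography comparator computed on the
same cohort, with dominance flags instead of ratios on the degenerate
quadrants.  Scenarios are simulated at a reference price of 0; because total
cost is affine in the per-test price with slope equal to the discounted
screen count S, the maximum cost-effective price is closed-form:
P* = P_ref + (λ·ΔQ − ΔC(P_ref))/S at threshold λ (default USD 50,000/QALY).
No price is reported when a scenario yields fewer QALYs than the comparator.

## Calibrated defaults

The generator's defaults are a stylised stand-in for a registry-calibrated
parameter set.  The declared calibration targets are the comparator's
screen-detected shares (DCIS 89%, invasive ~70%, combined 74%) and a ≳80%
drop in overdiagnoses when DCIS detection is switched off; the defaults were
fitted to those targets once and frozen:

| parameter | default | why |
|---|---|---|
| lifetime_bc_risk | 0.17 | lifetime onset risk incl. never-surfacing DCIS |
| onset age | TruncNormal(57, 10) on [30, 100] | diagnosis ages peak in the 60s after the preclinical lag |
| growth rate γ | Lognormal(median 0.465/yr, σ 0.25) | ≈1.5-year diameter doubling; σ kept tight — wide rate spreads length-bias screening toward indolent tumors and inflate invasive overdiagnosis |
| detectability Weibull shape | 2.0 | unidentified; exposed in config |
| d_clinical | Lognormal(median 2.6 cm, σ 0.30) | symptomatic sizes; with γ gives the ~2.6-year screen-to-clinical sojourn that yields 70% invasive sensitivity at biennial rounds |
| d_fatal | Lognormal(median 2.2 cm, σ 0.60) | sets the curable window; tuned for a sizeable but not saturated mortality reduction |
| DCIS onset fraction | 0.22 | reproduces the ~0.3 DCIS:invasive detection ratio |
| DCIS fates (regress, progress, clinical) | 0.40 / 0.38 / 0.22 | regression share drives DCIS-driven overdiagnosis |
| DCIS dwell | Exponential(mean 2.1 yr) | with 91%/round detection gives the 89% DCIS screen-detected share |
| survival after fatal crossing | Exponential(mean 3 yr) | typical advanced-disease survival scale |

## What the synthetic world does and does not establish

The generator emulates the *structure* the analysis needs — per-tumor
threshold diameters, a three-fate DCIS compartment, competing other-cause
mortality, parallel universes — not any registry's incidence or test
performance: there is no age-dependence in test characteristics or growth
rates, no birth-cohort trends, no correlation between thresholds beyond the
shared growth curve.  Green tests therefore establish internal correctness
(conversion arithmetic, ledger identities, monotonicities, calibration
recovery, directional structure of the benefit/harm table), not the absolute
per-1000 magnitudes a registry-calibrated production model would report:
here mortality reduction (~37% for the comparator), QALYs gained and
overdiagnosis levels differ from such published values by design-scale
factors, and only their orderings across scenarios are asserted.

## Numerical choices

* All event times are closed-form crossing ages; equalities in tests are
  exact where the arithmetic is exact (null-screening equivalence is
  bitwise).
* Ties: a tumor exactly at its fatal diameter at diagnosis is *not* cured;
  a diagnosis exactly at the death age does not count; stage boundaries are
  lower-inclusive.
* Diagnosis-window counting is [50, 75), so detections at the age-74 round
  are included.
* Integer percentages round half-up (the convention of the published
  tables), not banker's rounding.
* Seeds: every stochastic component draws from a named
  `SeedSequence(seed, spawn_key)` substream; draw counts per round are fixed
  (uniforms are consumed unconditionally) so results are invariant to which
  branch a woman takes.
* Cohort sizes: default 10⁶ (a registry-scale production analysis would use
  10⁷); acceptance-style checks run at 2×10⁵, where the combined-sensitivity
  Monte-Carlo standard error is ≈0.3 percentage points.

## Known limitations

Single tumor per woman; no age-dependent test performance; no treatment
effect beyond the stage mapping; no probabilistic sensitivity analysis
(the Bernoulli FP mode is a hook, not a PSA); costs and utilities enter as
point values; the life table is synthetic.  Alternative schedules (annual,
different age ranges) are expressible in config but not validated against
any external benchmark.
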