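# bcscreen

A desk-scale microsimulation of breast cancer screening for evaluating novel
screen tests — in particular, blood-based (liquid-biopsy) tests whose
sensitivity and specificity are still hypothetical.  It is aimed at
researchers in cancer-screening evaluation and health-technology assessment
who want a transparent, fully seeded model of the whole chain from tumor
natural history to threshold test prices.

## The model

Each simulated woman (a 1970 birth cohort, outcomes counted from age 30)
receives an other-cause death age from a life table and, with lifetime
probability *p*, one breast tumor.  A tumor starts at diameter 0.01 cm and
grows exponentially, d(t) = 0.01·e^{γt}, with a per-tumor rate γ.  Each
tumor carries three personal threshold diameters:

* **d_screen** — screen-detectability: a screen finds the tumor once
  d(t) ≥ d_screen.  d_screen is Weibull-distributed with median equal to the
  test's *median tumor size for screen detection*, the knob that sets a
  test's sensitivity for invasive disease.
* **d_clinical** — the size at which the tumor surfaces symptomatically.
* **d_fatal** — the *fatal diameter*: a tumor diagnosed while
  d < d_fatal is cured; past it, breast-cancer death is already determined
  (it follows the crossing by a sampled survival time, censored only by
  other-cause death).  Earlier detection saves lives purely by beating this
  crossing.

A fraction of tumors begin as ductal carcinoma in situ (DCIS), which during
a pre-clinical dwell may **regress**, **progress** to invasive disease, or
surface as **clinical DCIS**.  A screen detects pre-clinical DCIS with
probability equal to the test's *DCIS sensitivity*.

Screening follows a parallel-universe design: every woman's history is
resolved twice — without screening and under a screening policy (default:
biennial at ages 50–74, 13 rounds, full attendance) — with shared random
draws, so mortality reduction, overdiagnoses (screen-initiated diagnoses of
cancers that would never have surfaced), and false positives are measured
woman by woman.  Health states map to utility decrements and 2020-USD costs
(screens, false-positive work-up, diagnostics, stage- and phase-specific
care), discounted at 3%/year to age 30.  For each candidate test the package
reports discounted QALYs and costs, the ICER against digital mammography
(91% DCIS sensitivity, 1.21 cm median detection size, 88% specificity,
USD 149/test), and the **maximum per-test price** at which the candidate
stays cost-effective at USD 50,000/QALY — obtained in closed form because
total cost is affine in the per-test price.

## Worked example

Run the digital-mammography comparator on 200,000 women:

```sh
bcscreen run --n 200000 --seed 1 \
    --dcis-sensitivity 0.91 --median-detect-size 1.21 --specificity 0.88 --price 149
```

```
sensitivities: DCIS 89%, invasive 71%, combined 75%
mortality reduction: 37.4%
false positives per 1000: 1310.0
overdiagnoses per 1000: 9.2
QALYs gained per 1000: 95.0
total discounted cost per 1000: USD 4,032,582
```

The sensitivities are the share of cancers diagnosed at ages 50–74 that were
found by screening (the conversion currency for comparing test modalities);
the defaults are calibrated so the comparator's combined sensitivity is 74%
in expectation.  The remaining rows are per-1000-women lifetime outcomes
versus no screening on the same histories: screening averts about a third of
breast-cancer deaths here, at the price of ~1.3 false positives per woman
over 13 rounds and ~9 overdiagnosed cancers per 1000.

The full experiment — the comparator plus a 54-scenario grid of liquid-biopsy
test characteristics (DCIS sensitivity 0% or 91%; median detection size
0.01–1.39 cm; specificity 88/96/100%) — with detection-proportion,
outcome/price, and ROC-overlay tables:

```sh
bcscreen grid --n 1000000 --seed 1 --out results/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds a 200,000-woman cohort from the given seed, runs the comparator and
the default scenario grid on it end to end, and writes the results manifest
to `--out` (plus the full per-scenario grid summary next to it).
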