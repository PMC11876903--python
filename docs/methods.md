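# Methods

`hccsim` is an individual-level discrete-time state-transition model of
hepatocellular carcinoma (HCC) screening in cirrhosis, built to reproduce a
published cost-effectiveness comparison of mailed screening outreach versus
usual care from the published inputs alone. This note records the model,
its assumptions, the calibration, and the design decisions taken where the
published description was silent or internally inconsistent.

## States and cycle structure

Seven states: compensated cirrhosis, decompensated cirrhosis, HCC
early/late undetected, HCC early/late detected, dead. Cycles are 6 months,
matching the semi-annual screening guideline; the default horizon is 10
years (20 cycles) for 10,000 patients per arm, 58% of whom enter
compensated.

Within a cycle, events apply in a fixed order:

1. **Tumor aging/progression.** An undetected early tumor remains
   screen-detectable for `early_dwell_cycles` cycles since onset, then
   progresses to late stage.
2. **Outreach charge** (outreach arm): the annual per-patient program cost
   ($32.45 in year 1, $21.90 after) is charged pro rata to every alive
   patient — outreach is a population mailing, independent of adherence.
3. **Screening and detection.** Each undiagnosed patient completes a screen
   with the arm's per-cycle adherence (0.23 usual care, 0.35 outreach). A
   screened early tumor is found with sensitivity
   `screen_sensitivity_early`; unscreened or missed early tumors may still
   surface incidentally (`p_incidental_early_percycle`); late tumors
   present symptomatically (`p_symptomatic_detect_percycle`). Detection
   triggers the stage-specific treatment-episode cost plus a diagnostic
   workup. False-positive screens are modeled only as a workup cost at a
   configurable rate (default 0, since no false-positive rate is printed).
4. **Mortality and accrual.** Death probability is `1-exp(-c/mean)` from
   the current state's mean survival (9.8/2.5/6.5/2.0 years; HCC-state
   mortality replaces, not adds to, cirrhosis mortality). Survivors accrue
   a full cycle of state utility and background care cost, decedents half a
   cycle (half-cycle correction); everything is discounted to the cycle
   midpoint at 3%/year.
5. **Transitions.** Compensated survivors decompensate (6%/year converted
   per-cycle); survivors in either cirrhosis state acquire HCC (2%/4% per
   year) and enter the early-undetected state.

Detection deliberately *precedes* the mortality draw: a patient dying of
advanced HCC is diagnosed at terminal presentation rather than dying
uncounted. Relatedly, a death in an undetected HCC state is booked as a
**terminal diagnosis**: it counts as a late-stage diagnosis and incurs the
late-stage episode cost (SEER-Medicare episode costs are dominated by the
initial and terminal phases of care), with no post-diagnosis QALY credit.
Both behaviors are config flags (`terminal_diagnosis`, on by default).
Without them the two arms diagnose systematically different *numbers* of
cancers, and since any diagnosis costs ≈ $175–204k, the published result —
where the outreach arm's advantage is a pure late-to-early *stage shift* at
equal totals — cannot arise in any parameterization.

## Outcome accrual: `lifetime` (default) vs `horizon`

Two accrual conventions are implemented (`SimulationConfig.accrual`):

* **lifetime** (default): at diagnosis the patient is credited the expected
  discounted post-diagnosis QALYs, `u_s/(λ_s+ρ)` with `λ_s = 1/mean
  survival` and `ρ = ln(1.03)`, and the stage's treatment-episode cost, and
  leaves the cycle loop. Pre-diagnosis person-time is simulated within the
  horizon. Tumors still undiagnosed at the horizon are resolved
  analytically (expected discounted continuation of the detection cascade
  with incidental/symptomatic detection only — the organized program ends
  at the horizon — identical in both arms), and the remaining
  within-horizon program cost of a diagnosed outreach patient is charged as
  an expected discounted annuity. Background (cirrhosis) person-time
  truncates at the horizon identically in both arms and cancels under
  common random numbers.
* **horizon**: every patient, diagnosed or not, is simulated cycle by cycle
  and all accrual stops at the horizon; per-patient discounted QALYs are
  bounded by the horizon length.

The lifetime convention is the default because the published differences
are only attainable when stage-specific expected survival is credited in
full at diagnosis: the printed QALY gain of 300 per 108 extra early
diagnoses implies ≈ 2.8 QALYs per stage-shifted patient, which is
essentially `0.67/(1/6.5+ρ) − 0.52/(1/2+ρ)` = 3.64 − 0.98 ≈ 2.66 — the
*lifetime* QALY gap between an early and a late diagnosis — while
within-horizon accrual caps the achievable gain near half of that and makes
the published 5-year figures unreachable altogether. The printed treatment
costs are likewise lifetime episode costs. Both modes share all other
machinery and are cross-checked against a scalar per-trajectory reference
implementation and a deterministic expectation oracle.

## Utilities and care costs

Stage-based utilities apply to HCC states whether or not the tumor is
detected (0.67 early, 0.52 late), consistent with stage-specific survival
applying while undetected; cirrhosis states use 0.80/0.65. Undiagnosed
patients accrue an annual background care cost by underlying cirrhosis
state (a calibrated value; post-diagnosis care is covered by the episode
cost). All costs are 2021 US dollars; `cpi_adjust` is a single scalar hook
for re-basing the calibrated (unprinted) cost values.

## Adherence and patient out-of-pocket costs

Adherence is an independent per-cycle Bernoulli draw, not a persistent
patient trait — a persistent-trait reading caps the achievable
early-detection fraction below the published outreach-arm value. Patient
out-of-pocket cost per completed screen is travel (`$0.16/mile × 20
miles`) plus expected lost wages (30% employment × 3 h × wage × 1.276
benefits load), with a default wage of $28.50/h (approximate 2021
Dallas-area mean). The annualized figure exposed by
`expected_annual_oop` defaults to one counted screening opportunity per
year (annual out-of-pocket ≈ $12.6 at outreach adherence, matching the
published ≈ $13/year); strict semi-annual accounting (`2 × adherence`
screens/year) doubles it.

## Calibration of unprinted parameters

The published appendix (model diagram and several inputs) is unavailable.
`hccsim.calibration` recovers `UnprintedParams` by minimizing a weighted
sum of squared relative deviations between model outputs and the published
base case: early-stage diagnoses by arm (331/223), per-patient discounted
costs ($25,106/$25,291), per-patient QALYs (3.19/3.16), and the between-arm
differences (−$1,851,025 / +300 QALYs). Candidates are scored on the
deterministic expectation oracle (exact cohort expectations, noise-free,
~ms per evaluation) — a strict improvement over simulation-based scoring
with the identical estimand — then verified by a 50,000-patient
common-random-numbers simulation. The search is a coarse grid over the
integer dwell time with bounded Nelder–Mead refinement; weights emphasize
the detection counts (which identify the mechanism) and the cost levels.
Two a-priori constraints: incidental detection stays positive (the source
model includes it), and decompensated care cannot cost less than
compensated care.

Shipped fit (`data/calibrated_defaults.yaml`): dwell = 1 cycle,
screening sensitivity ≈ 0.98, incidental detection 0.002/cycle, symptomatic
detection of late tumors ≈ 1.0/cycle, care costs ≈ $1,236 / $3,831 per
year, workup fixed at $1,000 (a typical contrast-imaging diagnostic
evaluation; freeing it alongside two care costs against two cost anchors
would be underdetermined). The fitted sensitivity and symptomatic rates are
*effective* values absorbing structural simplifications (e.g. per-cycle
adherence, single-pass screening) and sit above literature estimates for
ultrasound sensitivity; they should be read as calibration outputs, not
clinical claims. The reduced-form detection fallback
(`detection_mode="reduced_form"`, stage assigned at onset by 0.67/0.33
given screening status) is retained for comparison; its usual-care early
fraction is analytically 0.23·0.67 + 0.77·0.33 = 0.408, between the
published arm-level fractions 223/602 = 0.370 and 331/602 = 0.550, which is
why it cannot reproduce the arm counts and the mechanistic model is the
default.

### Residuals the calibration cannot remove

* **Incident HCC (602).** With the published incidence (2%/4%), baseline
  mix (58/42), decompensation (6%/year) and exponential mortality at the
  published survival means, expected onsets are ≈ 1,000 per 10,000 over 10
  years (≈ 545 from compensated person-time, ≈ 375 from baseline
  decompensated, ≈ 115 from converters). No unprinted parameter affects
  onsets; reaching 602 would need ~40% fewer person-years at risk, which
  would simultaneously drop per-patient QALYs to ≈ 2.2, contradicting the
  published 3.16–3.19. The anchor is reported with its ≈ +67% residual.
* **QALY levels and difference.** Per-patient QALYs land ≈ 2.9 (−9%) and
  the QALY difference ≈ 254 (−15%): the model discounts the stage-shift
  gain to onset time (mean onset ≈ year 3.5–4, factor ≈ 0.89) and prices
  the dwell-period offset, which the published same-instant arithmetic
  (300 ≈ 108 × 2.8) does not.
* **Program-cost person-time.** The published threshold results imply the
  mailing cost accrues over ≈ 5+ discounted person-years per enrollee,
  i.e. nearly no mortality attrition, while the published survival means
  imply ≈ 3.9 alive discounted person-years. Charging every *alive* patient
  (this package's reading) yields a cost break-even ≈ $70/patient/year
  (published: $60), an adherence-gain break-even ≈ 4.2 percentage points
  (published: >5), and a 22%-vs-25% ICER of ≈ $3–5k/QALY (published:
  $12,373) — same signs and orders, systematically more favorable to
  outreach at low adherence gains. No charging rule reconciles all three
  published thresholds with the published mortality at once.

The acceptance tests assert the published figures at their stated
tolerances and are expected to fail exactly on these documented residuals;
the fit report (`CalibrationResult.report()`) carries every anchor's
residual so each can be asserted independently.

## Synthetic cohort: what it does and does not emulate

The generator *is* the study population definition: 10,000 patients, 58%
compensated, homogeneous within state — no age/sex structure, no etiology
mix, no Child-Turcotte-Pugh C (excluded upstream at chart review), no
transplant dynamics, no treatment-modality granularity, no non-cirrhotic
hepatitis B. Decompensated patients remain screen-eligible. Passing tests
therefore show internal consistency with the published cohort-level
arithmetic, not forecast accuracy for any real panel with covariate
structure, secular trends in incidence, or heterogeneous adherence.

## Numerical choices

* Annual→cycle probability conversion `1-(1-p)^c`; exponential mortality
  from mean survivals; mid-cycle discounting at annual-compounded 3%;
  continuous-equivalent rate `ln(1.03)` inside closed-form lifetime lumps
  and annuities.
* Common random numbers: one pre-drawn uniform per patient × cycle × event
  channel, shared across arms and sweep grid points; arm deltas are exact
  functions of parameters given the substrate, so threshold curves are
  smooth and bisection is well-posed (the Monte Carlo half-width of the
  response is reported at the crossing).
* PSA: beta/gamma by method of moments from the printed (base, SD),
  triangular from (low, mode=base, high); draws violating cross-parameter
  invariants (early ≥ late utility and survival) are redrawn. The printed
  treatment-cost SDs (418/451 on ~$175–204k means) are implausibly tight
  but honored as published.
* Degenerate inputs: `horizon_years=0` returns all-zero outcomes; `p=1`
  converts to 1 for any cycle length; infinite survivals give zero
  mortality; a zero-width calibration space evaluates that single point.
* Bisection tolerance is relative (`1e-3`) on the parameter with a bracket
  sign-change precondition; ties in dominance classification at exactly
  zero delta fall to the cost sign.

## Known limitations

Beyond the cohort simplifications above: exponential survival within
states (no cure fraction for resected early HCC); a single early→late
progression step with integer dwell; screening detects only early-stage
tumors (late tumors present symptomatically at a calibrated, near-certain
per-cycle rate); outreach effect enters only through adherence (no
downstream navigation effects); no half-cycle correction on the lump
payoffs beyond midpoint timing; calibration is a point fit with residual
reporting, not a Bayesian posterior; and the published figures it targets
are themselves internally inconsistent in the three respects documented
above, so those residuals are irreducible by construction.
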