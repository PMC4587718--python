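# Methods

## Model structure

The model is a deterministic annual-cycle Markov cohort model over eight
health states:

| state | therapy | utility | annual follow-up cost |
|---|---|---|---|
| `WELL_ASPIRIN` | aspirin | 0.998 | — |
| `WELL_WARFARIN` | warfarin | 0.987 | — |
| `POST_STROKE_WARFARIN` | warfarin | 0.476 | 12 × $2,652 |
| `POST_STROKE_ASPIRIN` | aspirin | 0.426 | 12 × $2,168 |
| `POST_ICH` | aspirin | 0.400 | 12 × $4,690 |
| `POST_BLEED` | aspirin | 0.998 | — |
| `RECURRENT_STROKE` | warfarin | 0.120 | 12 × $2,652 |
| `DEAD` | — | 0 | — |

Within a cycle each live person experiences at most one *index event*,
drawn from mutually exclusive alternatives whose probabilities depend on
the current therapy: ischemic stroke (4.5 %/yr on aspirin; relative risk
0.48 on warfarin) or major hemorrhage (2.5 %/yr on warfarin; relative risk
0.59 on aspirin), the latter split 20 % intracranial (ICH) / 80 %
extracranial.  Each event has a fatal fraction (stroke: 17.9 % on aspirin,
8.2 % on warfarin; ICH: 36.4 %; extracranial bleed: 4.9 %).  Event-free
decliners on aspirin additionally convert to warfarin with the sub-cohort's
conversion probability applied to the event-free remainder.

Destinations implement the care rules: a stroke survivor starts (or stays
on) warfarin; a major bleed ends warfarin; ICH survivors carry a permanent
disability state; extracranial-bleed survivors spend one recovery cycle in
`POST_BLEED` and return to `WELL_ASPIRIN`.  Stroke survivors who stroke
again move to `RECURRENT_STROKE` (and remain there); a post-stroke warfarin
patient who survives an extracranial bleed moves to `POST_STROKE_ASPIRIN`
so the stroke history (utility, follow-up cost) is retained.  `DEAD` is
absorbing and accrues nothing.  There is no background all-cause mortality:
over a 5-year horizon in a trial-age AF population, event fatality
dominates, and adding life-table mortality would dilute the therapy
contrast the model is built to measure.

## Cycle accounting

Annual-cycle models leave several accounting conventions open; this package
fixes defaults and exposes each as a switch (`ModelSwitches`):

- **Event-year valuation.**  The event year is charged the pre-event
  therapy's drug cost and valued at the *destination* state's utility (a
  stroke year is lived mostly post-stroke).  A fatal event's year accrues
  zero utility.
- **One-time event costs** are charged in the event year.  Only fatal
  ischemic stroke has its own acute cost ($12,130); fatal ICH and fatal
  extracranial bleeds are charged the corresponding non-fatal one-time cost.
- **Follow-up cost stream** (`followup_accrual`, default `"mid"`): the
  12 × monthly cost of the post-stroke/ICH states is charged on mid-cycle
  occupancy — events fall mid-year on average, so the entry year is charged
  half a year of follow-up, and every subsequent year in the state a full
  year, through the horizon.  `"start"` and `"end"` charge none or all of
  the entry year instead.
- **Discount timing** (`discount_from`, default 1): cycle *t* is discounted
  by (1+r)^−(t+1), i.e. accruals fall at the end of each year.  Setting 0
  leaves the first year undiscounted.  The one-time genetic-test cost is
  charged at time zero, undiscounted, to every tested person.
- **No half-cycle correction** of state membership is applied; the
  destination-utility and mid-cycle follow-up conventions above are the
  explicit replacements.

These defaults are the package's calibration of structurally unidentified
conventions; with them the adherence sweep's incremental-cost column is
affine with slope ≈ $17,017 per adherence percentage point and intercept
≈ −$88,800 (cohort of 1000), placing the cost-saving threshold at 5.2 %.

## Strategies

Usual care: 1000 decliners start in `WELL_ASPIRIN`, converting at
2.5 %/yr.  Test strategy at adherence *a*: 400·*a* start in
`WELL_WARFARIN`; 400·(1−*a*) test-positive decliners convert at 5 %/yr;
600 test-negatives at 1.25 %/yr; every tested person pays the $100 test
cost.  The population-average conversion rate in the test arm at *a* = 0 is
therefore 2.75 %/yr, not 2.5 % — the asymmetric multipliers are not
rebalanced, by design.  Warfarin starters discontinue only after a major
bleed; spontaneous discontinuation is not modelled.

## Thresholds

Since ΔC(a) and ΔE(a) are affine in adherence (linear initial split,
linear engine — verified by superposition tests), the cost-effectiveness
threshold (smallest *a* with net monetary benefit ≥ 0 at the configured
willingness-to-pay, default $50,000/QALY) and the break-even threshold
(ΔC = 0) are unique roots, found by scalar root bracketing to an absolute
tolerance of 1e-5.

## Sensitivity analyses

Seven quantities carry ranges: aspirin stroke rate (0.03–0.06), warfarin
stroke RR (0.37–0.63), warfarin bleed rate (0.02–0.04), aspirin bleed RR
(0.50–0.70), test cost ($50–$200), a grouped multiplier on all drug and
event costs (0.5–1.5), and a grouped multiplier on the utilities of the
non-fatal event states (0.8–1.2; healthy-state utilities are never scaled,
and scaled utilities are clipped to 1).  Grouped quantities move as single
multipliers, not per item.  Fatality fractions and the ICH share are held
fixed (no ranges are defined for them).

The tornado analysis evaluates each quantity at its bounds, all else at
base, at a default adherence of 5.25 % (near cost-neutrality, where the
ICER is most sensitive).  The PSA draws all seven from triangular
distributions (mode at base, support at the range) for 10,000 trials at a
default adherence of 20 %, and reports cost-effectiveness-plane quadrant
fractions.  Variance contributions are squared Pearson correlations between
each parameter's draws and incremental net monetary benefit at the
configured willingness-to-pay, normalised to sum to one; this is a
first-order (correlation-based) attribution, adequate here because the
outcome is nearly linear in the inputs over their ranges.

The CHADS₂ stratification re-runs the comparison with the aspirin stroke
rate set per score level.  The packaged grid
(`data/chads2_default.yaml`) carries literature-derived default rates and
is a configuration input, not a model constant; conclusions about specific
scores inherit whatever grid is supplied.

## Microsimulation oracle and synthetic data

`afcea.microsim` realises the identical annual event process as independent
patient trajectories: sub-cohort membership is drawn from the arm's split,
then one categorical draw per cycle over {6 event variants, conversion,
event-free}, with costs, utilities and discounting accrued exactly as in
the cohort engine.  The cohort model is the expectation of this process, so
microsimulation means converge to cohort totals at rate 1/√n; the central
validation property asserts agreement within 3 standard errors at
n = 100,000 for the base case and perturbed configurations.

Each patient's RNG stream is keyed by (seed, patient id), so enlarging the
cohort never perturbs earlier patients — simulations are reproducible and
stable regression targets.  The generator emulates only what the cohort
model states: therapy-specific annual event probabilities, fatality splits,
and switching rules.  It has no patient heterogeneity beyond test status
and sub-cohort (no age, sex or per-patient risk scores), no within-year
event timing, and no secular trends; agreement between engine and simulator
therefore validates the implementation, not the model's fidelity to any
real population.

## Numerical choices and degenerate inputs

Transition rows are validated to sum to 1 within 1e-12; event probabilities
exceeding unit mass raise an infeasible-model error.  Degenerate triangular
supports (low = high) return the point mass.  A PSA with zero outcome
variance reports undefined shares rather than NaNs.  Dominance is labelled
(`test_dominates` / `usual_dominates` / `equivalent`) and no ICER is
reported when the ratio is not meaningful.  Threshold searches return a
no-solution result (None) instead of raising when no crossing exists in
[0, 1].

## Known limitations

- Recurrent-stroke dynamics are coarse: `RECURRENT_STROKE` is absorbing
  among live states, and each further event there is tallied and charged
  anew.  Event tallies therefore distinguish *incident* (first-ever)
  strokes from the total including recurrences; the headline
  strokes-prevented count uses the incident tally, since the cohort is
  stroke-free at entry and the total would recount annual re-events from
  the absorbing recurrent state.
- Costs are fixed 2005 USD with no inflation adjustment; a global cost
  multiplier is the only lever.
- No neutral-to-harm adherence effects (warfarin starters are fully
  adherent thereafter), no test errors, no NOAC comparators, no
  half-cycle-corrected life expectancy beyond the conventions above.
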