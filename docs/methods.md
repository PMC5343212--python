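# Methods

`minutecost` implements the economic-evaluation chain for a two-arm
behavioral trial whose outcome is weekly minutes of moderate- to
vigorous-intensity physical activity (MVPA): itemized payer-perspective
costing, cumulative effectiveness by interpolation, cost-per-minute and
incremental cost-per-minute ratios, one-way deterministic sensitivity
analysis, an enrollment-scaling cost model, accelerometer bout scoring,
and a calibrated synthetic-trial generator.

## Costing model

Costs are micro-costed from the payer perspective (the program
deliverer): staff time at fully loaded wages, hardware, materials, and
recurring website costs. Research-only activities (assessments,
consent, compensation), recruitment, and website *development* are out
of scope — only delivery of an already-built program is costed.

**Loaded wages.** An hourly wage is the (fringe-loaded) annual salary
divided by the hours in a work year, quoted to the cent, then inflated
by an overhead fraction for shared space:

    hourly = round_cents(annual x (1 + fringe) / hours_per_year)
    loaded = hourly x (1 + overhead)

Defaults: a 2000-hour work year and 10% overhead. The bundled rates are
fringe-loaded annuals ($86,520 trainer; $56,153 research associate →
$43.26 and $28.08 per hour; $47.586 and $30.888 loaded). The annuals
are taken as canonical; the nominal "44% benefits" multiplier that
accompanies them in source material is treated as descriptive, because
it disagrees with the printed annuals at the ~$100 level.

**Hardware** is charged as straight-line depreciation,
`price x use_years / life_years` (defaults in the bundled ledger:
5-year life, 3 years of use; a $700 computer and $400 printer charge
$420 and $240).

**Ledger arithmetic.** Amounts are held in integer cents; whole-dollar
rounding happens only in report formatting. Each ledger line carries an
amount at the 6-month horizon and a cumulative 12-month amount
(`amount_12mo >= amount_6mo`). Because itemized inputs are published
rounded to whole dollars, column totals carry a ±$2 reproduction
tolerance. One convention deserves note: a line may be flagged
`in_cumulative_total = False`, meaning it appears in itemized displays
but is excluded from 12-month totals. The bundled ledger uses this for
the video library, matching the source ledger whose cumulative bottom
line ($14,781) omits that first-phase-only $150 purchase; the
convention also reproduces the published 12-month sensitivity cells,
which an inclusive total does not.

## Effectiveness

Arm-level mean weekly MVPA minutes are measured at weeks 0, 26, and 52
(completers only, unadjusted). The weekly rate is assumed to change
linearly between measurements, so the cumulative per-person gain over a
window is the trapezoidal integral of the interpolated weekly minutes
minus baseline. A single segment reduces to `(Δmean / 2) x weeks`. The
integral is computed on the union of window endpoints and interior
measurement weeks, which makes it exact for the piecewise-linear
interpolant and makes adjacent windows add exactly. Months are defined
as 26/6 weeks; this convention reproduces all published gain totals
(1362.4 / 715 / 4032.6 / 2306.2 minutes per person for self-report).
No extrapolation outside the measured range is permitted.

For the accelerometer measure, the trapezoid of the published
*rounded* weekly means (520.0 / 185.9 at 6 months; 1489.8 / 720.2 at
12 months) differs slightly from the published totals (523.0 / 186.3 /
1496 / 696); the unrounded inputs are unrecoverable, so downstream
ratios accept the published totals as overrides
(`datasets.ACCELEROMETER_GAIN_TOTALS`).

## Cost-effectiveness ratios

Per-arm: unrounded per-person cost divided by unrounded per-person
minute gain. Incremental (ICER): between-arm cost difference over
between-arm gain difference. Ratios are rounded to cents only at
reporting — rounding earlier changes the published cells. Zero
denominators raise an explicit error rather than producing infinities,
and a negative ICER is reported with a dominance flag naming the arm
that both costs less and gains more.

## Sensitivity analysis

One-way deterministic, ±20% by default:

* **Staffing costs** scale every staff-time line — training, delivery,
  *and routine website maintenance* (it is staff time) — in both arms.
  Including maintenance is what reproduces the published accelerometer
  cells ($0.19/$0.14 at 6 months); the shift in the ICER is exactly
  `(m − 1) x Δstaff-cost-per-person / Δgain`.
* **Intervention effectiveness** scales the minute gains of both arms,
  which is exactly reciprocal on the ICER: `ICER(x m) = ICER / m`.
  The implementation divides the unrounded standard ICER by the
  multiplier, so the identity holds to machine precision. One published
  grid cell (effectiveness −20%, 12-month accelerometer, $0.12)
  contradicts this identity applied to its own published standard row
  ($0.08 unrounded 0.0832 → $0.10) and is reproduced at the value the
  method yields.

## Enrollment scaling

The 12-month intervention ledger is split into fixed costs (hardware,
hosting, technical support, training) and variable costs (materials
plus delivery and maintenance staff time), with variable cost per
person calibrated at the enrollment observed in the trial (n=104).
Cost per person per month at enrollment n is

    (fixed + n x variable_per_person) / (n x 12)

which decreases strictly in n and approaches `variable_per_person/12`
(≈ $8.51 for the bundled ledger) with gap exactly `fixed/(12n)`. The
model varies the intervention arm only; this reading reproduces all
published curve values ($16 at n=50, $12 at 100, $10 at 200).
The fixed/variable split uses each line's full horizon amount — the
cumulative-display exclusion above does not apply, because a
first-phase-only item is still purchased once per participant.

## Accelerometer scoring

Minute-level vertical-axis counts are scored as MVPA inside bouts:
maximal runs of consecutive worn minutes at ≥ 1952 counts/min lasting
≥ 10 minutes. Runs break at non-wear minutes and at gaps in the minute
grid. Interruptions are not tolerated by default (the strictest
reading); an `interruption_allowance` knob merges runs separated by at
most k worn sub-threshold minutes, crediting only the above-threshold
minutes. Whether the 1952 cut-point applies to vertical-axis or
vector-magnitude counts is taken as vertical-axis (the conventional
usage). Wear flags are accepted as input; a ≥60-minute consecutive-zero
heuristic (`detect_nonwear`) is provided but not applied implicitly.
A week is valid with ≥ 10 h wear on ≥ 5 days, or ≥ 3000 total wear
minutes over ≥ 4 days with any wear (the second clause's day count is
read as days with nonzero wear).

## Synthetic trial generator

The generator reproduces the *conditions* of the emulated trial: arm
sizes 104/101, completer means/SDs at weeks 0/26/52 for both measures,
16.1% dropout equal across arms (completers 83.9%), and an eligibility
screen requiring baseline self-reported MVPA below 60 min/week.

**Marginals.** Weekly minutes are zero-censored (tobit) normals,
`max(N(mu, sigma), 0)`, with the parent moment-matched so generated
values reproduce the configured mean/SD. A zero-*truncated* normal
cannot represent these targets: the baseline coefficient of variation
(15/8 = 1.875) exceeds the truncated-normal supremum of 1, and naive
truncation of N(112.8, 97.1) would inflate the week-26 mean to ≈135.
Censoring instead puts realistic point mass at zero minutes (~35% of
an underactive population reporting no MVPA).

**Dependence.** Within a measure, timepoints share a Gaussian copula
on the latent scale with pairwise ρ = 0.4 (a plausible value for
repeated physical-activity measures; not a reported quantity).
Measures are generated independently. Both choices are configurable.

**Eligibility.** The baseline self-report parent is matched
conditional on the < 60 cap, and whole participants are rejection-
sampled on that event. Because the screen truncates the *latent*
baseline, correlated follow-ups would be biased low by several
minutes; follow-up parents are therefore matched conditional on the
screening event, integrating the censored-normal moments over the
truncated latent baseline by Gauss–Legendre quadrature (96 nodes).
With this correction every configured mean is recovered within 3
Monte-Carlo SEs at n = 5000/arm (the test suite checks all 12).

**Dropout** is assigned independently of all outcomes, so completer
and non-completer baseline means agree in expectation.

**Staff log.** Per-task time entries (orientation visits, 1-week /
1-month / 9-month calls with Poisson failed attempts at 3 min each,
6-month visits, per-cohort training, weekly website maintenance) are
drawn from a catalog calibrated so expected arm-level personnel costs
match the bundled ledger's personnel lines (e.g. delivery ≈ $5674
intervention / $1976 control in phase 1; training $471 = 6 h of joint
trainer+trainee time at loaded rates). Aggregating a log yields
personnel `CostItem`s directly.

What the generator does **not** emulate: within-person measurement
error of the PAR instrument, seasonal or weekday structure in counts,
informative dropout, site or interviewer effects, and any behavioral
mechanism of the intervention. Passing parameter-recovery tests shows
the pipeline is consistent under the stated model, not that the model
captures every feature of field data.

## Problem sizes and numerical choices

* Report rounding is half-up (accounting convention), via `decimal`.
* Parameter-recovery tests run at n = 5000/arm (≈2 s); the bout-scorer
  oracle test enumerates 1000 random streams of up to 400 minutes.
* The trapezoid–Riemann oracle comparison uses a 0.001-week midpoint
  rule and requires relative error < 1e-6.
* Moment matching solves a 2×2 system by least squares from several
  starts; failure to converge (e.g. a configured mean at or above the
  eligibility cap) raises a configuration error rather than sampling
  from a mismatched distribution.

## Known limitations

* No discounting, inflation adjustment, or taxes: a 12-month horizon
  needs none.
* No cost-per-QALY conversion or health-care-cost offsets; the
  effectiveness unit is a minute of MVPA.
* One-way sensitivity only — no probabilistic sensitivity analysis or
  acceptability curves.
* The ±$2 ledger-total tolerance means cent-level agreement with
  whole-dollar published tables is not claimed, only dollar-level.
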