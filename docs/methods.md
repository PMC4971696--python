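# Methods

## Outcome model

Measured systolic blood pressure for subject *i* at time *t* (years) is

    Y_it = a_i + b_i*t + c*X_it + d*Z_it + eps_it

- `a_i ~ Uniform(inclusion_low, inclusion_high)` — entry into a prevention
  trial is conditioned on a screening threshold, so baseline long-term BP is
  uniform over the inclusion window rather than normal. Default window
  125–140 mm Hg (a prehypertensive cohort).
- `b_i` — long-term trend, mm Hg per year. The model admits
  inter-individual slope variation `b_i ~ Normal(trend, slope_sd^2)`, but
  the study scenarios fix the trend (0, 1 or 2 mm Hg/yr), so `slope_sd`
  defaults to 0 and the trend is deterministic. This reproduces the stated
  scenario grid while keeping the random-slope model form available.
- `c` — additive effect while on treatment (negative lowers BP); scenario
  values −5 and −10 mm Hg.
- `Z_it` — carryover weight: 0 before and during treatment, 1 at treatment
  cessation, decaying linearly to 0 over the carryover duration `D` years;
  identically 0 when `D = 0`. A renewed treatment period resets it.
- `d` — carryover magnitude. Its numeric link to `c` is a free choice; the
  default `d = c` makes BP return to trend *continuously* from the full
  on-treatment level (a gradual return), and is independently configurable.
- `eps_it ~ N(0, sigma^2)` i.i.d. — a single combined measurement-error +
  intra-individual variability term; scenario values sigma = 3, 5, 7 mm Hg.
  Circadian/seasonal structure and correlated within-subject noise are
  deliberately not modelled.

Time is in years throughout; visit schedules of 3, 6 and 12 months are
encoded as intervals 0.25, 0.5 and 1.0. Visits run from one interval after
randomisation to the study horizon; the screening value at t = 0 is the
inclusion draw and never enters a diagnosis rule (it is below threshold by
construction, so counting it would be degenerate).

### Period boundaries

The on-treatment indicator of the low-level trajectory API uses half-open
intervals `[start, stop)`: at the stop time the subject is off treatment
and the carryover weight is exactly 1. The trial designs instead evaluate a
measurement taken exactly at a period boundary as reflecting the treatment
of the period it concludes (`boundary_on_treatment=True`): the blood draw
at a crossover visit happens before the switch, and the final visit of a
treated second period happens while still on drug. Without this convention
a subject treated in the second crossover period would be scored as
untreated at the very last visit, manufacturing spurious end-of-study
diagnoses. Carryover decay then starts strictly after the boundary visit.

## Diagnosis rules and censoring

Six rules against a strict `> 140` mm Hg threshold (a tie at exactly 140.0
never diagnoses — probability zero under the continuous model, but fixed
for determinism on crafted inputs):

| rule id           | condition (at visit k)                                  |
|-------------------|---------------------------------------------------------|
| `single`          | measurement above                                       |
| `two_consecutive` | visits k−1 and k both above                             |
| `mean_two`        | mean of visits k−1, k above                             |
| `any_three`       | third above-threshold visit (not necessarily consecutive) |
| `mean_three`      | mean of visits k−2, k−1, k above                        |
| `oracle`          | measured AND underlying (noise-free) above at visit k   |

`any_three` accumulates exceedances over the subject's entire observed
series — across treatment, post-treatment and crossover periods — because
the criticised real-world rule accumulated over the whole trial; it does
not reset at crossover. Mean-window rules use only observed measurements,
so no diagnosis is possible before the window fills. The oracle rule is a
pointwise conjunction at a single visit; it is infeasible in practice but
isolates the contribution of measurement noise to false diagnosis.

A subject is censored at the first diagnosing visit (they start open-label
treatment, making later measurements unusable); implementation-wise the
earliest-hit scan guarantees no later measurement affects any result.

## Designs

- **Parallel**: treatment arm on drug over `[0, treatment_years]`, then
  carryover; control arm never treated. Horizon = treatment + follow-up.
  The post-treatment window is not pinned by the scenario grids; it
  defaults to 2 years (the motivating trial's follow-up), configurable.
- **Crossover**: two periods of `period_years` (default 2, the motivating
  trial's treatment length; horizon 4); one arm treated first, the other
  second. Subjects diagnosed in period 1 contribute nothing to period 2.
  Per-period event counts are attached (a boundary-visit diagnosis at
  t = period counts to period 1).
- **Combination**: the crossover's two arms plus a never-treated arm —
  meant to let the parallel design's positive bias and the crossover's
  negative bias cancel.

Arms are independent cohorts (simple randomisation, no pairing). The
primary comparison is cumulative incidence at the end of the full horizon;
the tested contrast is treatment vs control (parallel) or treatment-first
vs treatment-second (crossover and combination).

## Test statistic

Analytic route: simulate one large cohort per arm (default 100,000
subjects, making the Monte-Carlo error in an incidence < 0.2 percentage
points and negligible next to the test's own sampling variation), then
plug the incidences into the normal-approximation two-proportion power
formula — pooled-variance critical value, unpooled-variance alternative,
both tails summed, no continuity correction — at the trial's per-arm size
(default 405 ≈ half of the motivating trial's 809 randomised) and
alpha = 0.05 two-sided. This variant returns *exactly* alpha at p1 = p2,
which makes the oracle-rule nominal-size check clean. With both incidences
degenerate at 0 or 1 the statistic is undefined and the rejection
probability is reported as 0 (logged).

Empirical route (`empirical_rejection_rate`): simulate replicate trials at
the test sample size and run the pooled two-proportion z-test on each;
used to cross-validate the analytic shortcut. Agreement is judged within
3 binomial standard errors of the replicate count plus the analytic
value's sensitivity to the ±3 SE incidence-estimation error (propagated
through the power formula by finite differences).

## Random-number policy

All randomness flows from `numpy.random.Generator`s. Grid cells derive
independent substreams via `SeedSequence((root_seed, cell_index))`, with
cell indices tied to the full grid enumeration, so results are independent
of execution order and of subsampling, and interrupted grid runs resume
bit-identically. Within a cohort the draw layout is fixed (intercepts,
then slopes when `slope_sd > 0`, then the noise matrix; subject *i* owns
row *i*), so a fixed seed reproduces every trajectory exactly.

## Grid presets

- `fig3` — parallel false-positive sweep: rules {single, two_consecutive,
  mean_two, mean_three} × sigma {3,5,7} × treatment length
  {1,1.5,2,2.5,3} yr × interval {0.25,0.5,1}, trend 1, no carryover
  (180 cells). The any-three and oracle rules are reachable via overrides.
- `fig4` — inclusion-criteria sweep: lower bound {110,120,130} × effect
  {−5,−10} × carryover {0,…,2} yr × interval, 2 yr treatment, trend 1,
  sigma 5 (90 cells). The quantity of interest is the incidence
  *difference*; no formal test is attached to this sweep.
- `fig5` — crossover Type I error: five feasible rules × sigma {3,5,7} ×
  trend {0,1,2} × interval, no carryover, 2-yr periods (135 cells).
- `combination` — the three-arm design over the fig5 coordinates.

The fig3/fig5 sweeps fix the treatment effect at −10 mm Hg (the headline
scenario's value; the sweeps' source grids do not pin it) and fig4 uses the
two_consecutive rule; both are overridable. No multiplicity adjustment is
applied across cells — per-cell rates are reported raw.

## Problem sizes and numerical choices

Default cohorts of 100,000 per arm run a scenario in well under a minute;
the qualitative-trend checks over the 180-cell parallel grid use 20,000
per arm, where a 0.02 tolerance (a few Monte-Carlo standard errors of a
Type I error near 0.5, plus saturation flatness near 1) with at most one
tolerated violation per trend line separates sampling noise from a real
monotonicity failure. Replicate-based cross-validation uses 2,000 trials
per scenario. Horizon/interval visit counts are computed with a 1e-9
guard against binary-representation edge cases; all scenario intervals
(0.25, 0.5, 1.0) are exactly representable.

## What the generator does and does not emulate

The simulated cohorts reproduce the structural mechanism — threshold
diagnosis of a noisy, trending measurement with censoring at diagnosis —
under idealised conditions: univariate systolic BP only (no joint
systolic/diastolic criterion), i.i.d. Gaussian noise, constant treatment
effect, full adherence, no dropout, no visit-time jitter. Passing tests
therefore demonstrate the *bias mechanism* and the designs' operating
characteristics under the stated model, not the numeric incidence of any
real trial; real-data features such as correlated noise, time-varying
effects, and bivariate thresholds would change magnitudes (a bivariate
criterion is expected to make the designs perform worse, not better).

## Known limitations

- Power and carryover-magnitude estimation are computed by the same
  machinery (nonzero `carryover_years` turns the rejection probability
  into power) but no power sweeps are bundled, since none of the
  qualitative conclusions depend on them.
- The mixed-model (MAR) analysis route suggested by the censoring
  structure is out of scope; the package evaluates design-based incidence
  comparisons only.
- Survival-analysis tests (log-rank, Cox) on the diagnosis times are not
  implemented; the contrast is cumulative incidence at the horizon.
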