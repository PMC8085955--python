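# Methods

## The problem

Collection digitization is performed by technicians — typically
undergraduates with no prior collections experience — who report, per
work session, the task performed, minutes worked, specimens processed
and any setbacks. Task throughput (specimens per minute, SPM) improves
with practice, so the labor needed to digitize N specimens depends on
how technician time is organized: many short appointments keep everyone
near the bottom of the learning curve. `digilabor` models this with
three components: a cleaning procedure for the session logs, an
experience-binned rate model per task, and a turnover-constrained labor
simulator.

## Rate curves

For each primary task, session rate is modelled as a function of the
technician's cumulative hours on that task, *x*, attributed at report
submission (the session's own minutes are included in *x*). The
canonical curves and limits are:

| task | form | curve (SPM) | limit |
|---|---|---|---|
| imaging | linear | 1.95170 + 0.02118·x | ≤ 4.00 |
| skeletal databasing | linear | 2.55659 + 0.02760·x | ≤ 6.50 |
| barcoding | quadratic | 3.7216 + 0.09928·x − 0.00175·x² | ≥ 3.00 |

Curves are fit on two-hour experience bins: every kept session with
*x* < 64 h lands in one half-open bin [2k, 2k+2), and the unweighted
mean bin rate is regressed on the bin midpoint (ordinary least squares;
`scipy.stats.linregress` for lines, `numpy.polyfit` for the quadratic).
The 64-hour threshold reflects thinning participation at higher
experience; the rate limits prevent extrapolating unrealistically fast
(or slow) technicians beyond the data. Design choices here that the
problem leaves open: the abscissa is the bin midpoint (the symmetric
choice), fits are unweighted across bins, and fitting uses bin means
rather than raw sessions. The canonical coefficients above — not refit
values — are the defaults used by the projection stage, so projection
correctness does not depend on any particular data set; a fitted model
set can be substituted (`model_source: fitted`).

## Turnover simulation

Labor projections advance in whole hours. During a technician's k-th
hour on a task (k is 1-based within their contract) they produce
`60 × clamp(f(min(k, 65)))` specimens, where `f` is the task curve and
`clamp` applies the task's rate limit. The experience argument freezes
at 65 — the curve is followed through the hour that *ends* one step past
the 64-hour bin threshold and held constant afterwards. Every
`contract_duration` hours the technician is replaced: k resets to 1
while cumulative production carries over. The projected labor for a
target count is the first hour at which cumulative production meets it,
reported as an integer. The "combined" figure sums the three per-task
simulations at the same contract duration (contract durations are
task-specific: a technician splitting 90 hours evenly across three tasks
has a 30-hour per-task contract). The simulator always terminates
because every hourly rate is bounded below by a positive clamp.

The hour-stepped accumulation is checked in the tests against an
independent closed-form oracle (arithmetic/power-sum series with the
clamp breakpoints computed analytically) to 1e-9 relative; the full
default grid (6 durations × 13 counts × 3 tasks + combined = 312 cells)
is checked cell-for-cell against the packaged reference table.

`retention_savings` compares the combined hours of the shortest and
longest contract durations at one specimen count:
(H_short − H_long) / H_short. On the default grid at 500,000 specimens
this is ≈ 0.192.

## Cleaning

Five exclusion stages run in a fixed order; each entry is claimed by
the first stage that matches. Entry counts and hour totals are audited
per category, and the partition is conserved (kept + excluded = input).

1. **Non-representative reporters** — supplied as a configured list of
   reporter ids. These are found by human investigation (fraud,
   additional duties, suspect reporting), not by an algorithm; when the
   synthetic generator provides ground-truth labels, the pipeline folds
   its flagged reporters into this list.
2. **Non-representative workflow** — a configured list of entry ids,
   for the same reason.
3. **Swapped-field entry errors** — an entry whose rate
   (specimens/minute) falls below its task's low-rate quantile (default
   5th percentile) *and* whose inverse ratio (minutes/specimen) lies
   within 2 rate-SDs of the task's mean rate: the numbers are only
   plausible if the two fields were exchanged. Zero-specimen entries are
   never classifiable as swapped. The per-task statistics are computed
   on the survivors of stages 1–2 minus whitelist-classified setbacks
   minus provisional 5-SD field outliers, so a few corrupt values cannot
   distort the typical-rate bands. Plausibly low-but-honest rates are
   safe: the inverse of any rate above ~1 SPM is below every task's
   tolerance band, so the inverse-match condition, not the quantile
   trigger, is the discriminating test.
4. **Setbacks** — free text is normalized (lowercased, punctuation
   removed, whitespace collapsed) and compared against an
   acceptable-phrase whitelist (default {"no", "none", "no setbacks"}).
   Non-blank, non-whitelisted text marks a setback session. Blank text
   counts as "nothing to report". Training sessions are deliberately not
   whitelisted, so initial training time is excluded from rate fitting.
5. **Extreme outliers** — minutes or specimens strictly exceeding 5 SDs
   of the field's per-task distribution among the survivors of stages
   1–4 ("exceeding" is strict; zero-variance or single-entry fields
   yield no flags; SDs use ddof=1).

Re-cleaning the kept partition excludes nothing further in stages 1–4;
stage 5 can in principle move because its means/SDs are recomputed on
the reduced population (tested and documented rather than hidden).

## Synthetic session generator

The generator emulates the statistical structure of a multi-herbarium
project's session logs. Defaults, with rationale:

- **105 technicians, 5–60 sessions each** (~3,400 entries): the scale of
  a multi-year, multi-collection effort; enough entries that 2-hour bins
  up to 64 h are populated.
- **Session minutes** ~ Normal(101, 35) truncated at ±2.5 SD and rounded
  to the nearest 5 (reporters are told never to round beyond 5 minutes);
  101 minutes matches the typical undisturbed session.
- **Task mix** {barcoding 0.15, imaging 0.30, databasing 0.25, other
  0.30}, with 70% "stickiness" to a per-technician primary task —
  technicians specialize, which is also what produces deep per-task
  experience for the upper bins.
- **Clean rates**: the task's canonical curve evaluated at cumulative
  hours at session end, times multiplicative lognormal noise with CV 0.10
  (rates are positive and right-skewed), truncated at ±2.5 SD; specimens
  are rounded to whole counts. "Other" (curation-type) sessions process
  zero specimens.
- **Setbacks** (probability 0.15): reported minutes are inflated ×1.32
  with no extra production — calibrated so mean setback-session duration
  ≈ 133 min vs ≈ 101 min undisturbed — and the free text is drawn from a
  non-whitelisted phrase pool (camera, internet, training, portal, …).
  Setback and outlier distortions do not feed the generator's own
  experience accumulation (lost time is not practice).
- **Swapped fields** (≈1% of clean primary entries): minutes and
  specimens exchanged. Candidates are restricted to entries whose clean
  rate is within 1 SD of the realized task mean, so that after the swap
  the inverse ratio is unambiguously typical — the anomaly the stage-3
  rule is defined to catch. (An entry swapped from an atypical rate is
  genuinely indistinguishable from an honest slow session, so injecting
  it would make the labels wrong, not the detector.)
- **Extreme outliers** (≈2%): either minutes set to ~8–10 minutes per
  specimen (≥ 3,000 min; a timer left running) or specimens set to
  4,000–5,000. The ranges are homogeneous so that no injected outlier is
  masked below the 5-SD threshold by larger ones inflating the field SD,
  and the minutes-outlier inverse ratio always lies far above every
  task's rate band so the swap rule cannot claim it.
- **Fraudulent reporters** (2) emit rates uniform in [0.3, 9] SPM,
  uncorrelated with experience; **workflow entries** (3) are ordinary
  entries flagged as produced under an atypical workflow.

By construction the labels are separable: on default fixtures the
cleaning stages recover every injected anomaly with precision and recall
1.0 (verified across seeds). That is a property of the generator design,
and it bounds what these tests show about real data — real setback text
is messier, real outliers are not guaranteed to clear 5 SDs, and real
swapped entries can originate from atypical rates. What the synthetic
results do establish is that each rule implements its definition
exactly and that the pipeline's bookkeeping (ordering, conservation,
audit) is correct.

## Productivity accounting

Because every specimen passes through all three primary tasks, "total
specimens digitized" is the arithmetic mean of the three per-task
specimen totals. Three project-wide rates divide it by different hour
totals: (A) pre-cleaning hours on all tasks, (B) post-cleaning hours on
all tasks, (C) post-cleaning hours on primary tasks only. All rate
functions return unrounded values; the report writer rounds task rates
to 2 decimals and project-wide rates to 3, so presentation conventions
are quarantined from the arithmetic.

## Numerical notes and limitations

- The simulator evaluates hourly rates as a vectorized cumulative sum
  (sequential accumulation order) and finds the first hour meeting the
  target with a left binary search; ties (production exactly meeting the
  target) count that hour.
- Problem sizes in the tests are deliberately modest — default synthetic
  fixtures of a few thousand entries, parameter-recovery runs with 50
  single-task technicians — chosen as the smallest scales at which bin
  coverage spans the full 0–64 h range.
- Session dates are generated with day resolution; two sessions by one
  technician never share a date, so date sorting is a total order per
  reporter. On real data, same-day sessions fall back to input order
  (stable sort).
- The projections are deterministic: technician heterogeneity,
  stochastic setbacks and non-task hours are not simulated. Cleaning
  removes setbacks and training before fitting, so the curves describe
  undisturbed throughput; real budgets should add a setback/overhead
  buffer (on the synthetic defaults, setbacks alone are ~15% of entries
  and a larger share of hours).
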