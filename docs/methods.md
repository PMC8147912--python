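# Model and methods

This note documents the simulation model implemented in `pcsim`: its
entities, the event flow, the stochastic submodels with their parameters,
the indicator definitions, the statistical machinery, and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and assumptions

The simulator covers a closed regional primary care system: an adult
patient population and a roster of primary care practices. Deliberately
excluded: pediatric care, gender differences, no-shows, infection dynamics
or cross-effects between illnesses, treatment-dependent illness durations,
referrals to specialists or hospitals, home visits, insurance distinctions,
physician absence, seasonality, and holidays. Ratings are private to each
patient (no word of mouth).

## Time

Time is continuous in days. A `TimePoint(day, frac)` doubles as a duration;
the scalar value `day + frac` orders all time objects (comparison tolerance
1e-9 days ≈ 0.1 ms). Each day has a morning and an afternoon session;
sessions are equivalent when their days agree mod 7 and their halves match,
giving 14 weekly session classes. **Day 0 is a Monday** — this anchors which
classes are weekends, which the default rosters keep closed.

## Agents

**Patients** carry a constant location (WGS84 degrees), health condition
`c ∈ [0,1]` (0 = perfectly healthy), age class, weekly session
availabilities (one flag per weekly class), and consideration set; and a
variable set of acute illnesses, at most one acute appointment, an
emergency flag, per-practice appointment ratings, per-(practice, weekly
session) walk-in ratings, and — for chronic patients — one constant chronic
illness, a regular appointment, and a family physician.

**Practices** carry a location, weekly opening hours (possibly closed per
session), an uncapacitated waiting room, and three pluggable strategies
(scheduling, treatment, admission) drawn from named registries.

### Ratings

Initial ratings blend distance and schedule fit:

    r = w_dist · 1 / (1 + d / d0)  +  w_match · overlap

with `d` the great-circle distance, `d0 = 5 km`, `w_dist = w_match = 1`, and
`overlap` the fraction of the patient's available weekly sessions in which
the practice is open. Walk-in ratings start from the same value per session
and are zero where the practice is closed or the patient unavailable.
Experiences rescale the touched rating multiplicatively (configurable):
request granted ×1.1, request failed ×0.8, short wait (≤ 30 min) ×1.05,
long wait ×0.9, rejected at the door ×0.6; ratings are capped at 100 and
floored at 0. Only the monotone directions of these updates are normative;
the kernel and factors are package choices. The consideration set is the
k = 5 nearest practices, fixed at initialization. Chronic patients anchor
to the top-rated practice as family physician and reconsider after each
regular visit, switching only when a challenger's rating exceeds the
incumbent's by 20 % (hysteresis keeps chronic care continuous).

## Illness machinery

A family defines linear functions of seriousness `s`: expected duration
`D_f`, expected willingness to wait `W_f`, follow-up interval `N_f` (any of
`D_f`, `N_f` may be inapplicable), and a chronic flag. Evaluations are
clamped at zero with a warning. Traits of an emerging illness:

| quantity | distribution | parameters |
|---|---|---|
| onset gaps | exponential | rate `I_a(c)` per 365 days |
| family | categorical | age-class-illness table row |
| seriousness | triangular on [0,1] | mode 0.3 |
| duration | log-normal | mean `Δd_a · D_f(s)`, CV 0.25 |
| willingness | Weibull | mean `Δω_a · W_f(s)`, shape k = 2 |
| follow-up | deterministic | `ν = N_f(s)` |

The dispersion parameters (triangular mode, CV, Weibull shape) are package
choices — the trait means are structural, their spread is not — and are
exposed in `SamplingConfig`; `deterministic=True` collapses every draw onto
its mean for hand-checkable runs. Age-class factors multiply the family
means. Chronic illnesses are sampled analogously from the chronic table but
never carry a duration; a patient has at most one, fixed for the whole run.

## Event flow

Events process chronologically; simultaneous events order by a fixed kind
priority (illness dynamics < arrivals < treatment completions < session
close < end-of-buffer bookkeeping), then insertion order — runs are
bit-reproducible for a given (scenario, horizon, seed). Randomness splits
into five named substreams (onsets, illness traits, service times,
arrival/punctuality, choices) derived from the root seed, so changing one
concern leaves the others' draws untouched.

* **Onset.** The patient adds the illness, schedules its recovery, and seeks
  care. An existing acute appointment inside the willingness window is
  reused (one acute appointment per patient, and every appointment treats
  all acute illnesses); otherwise up to two requests in rating order, each
  answered instantaneously with the earliest free slot inside the window
  and the patient's availabilities. If both fail, the walk-in path targets
  the feasible (practice, session) pair with the highest walk-in rating,
  earliest session on ties.
* **Walk-in feasibility.** The willingness window bounds appointment offers;
  the walk-in fallback extends past it day by day (up to 14 days) to the
  next feasible session — patients who cannot get an appointment still seek
  treatment. A patient forgoes care only when rejection retries exhaust all
  considered practices or no availability overlap exists at all. Without
  this extension, short willingness draws plus weekend closures make a
  material share of patients forgo care, and widening the willingness
  window then *raises* treatment counts — inverting the documented
  sensitivity direction (see below).
* **Recovery.** The illness is removed. If no acute illness remains, a
  pending booking or walk-in plan is cancelled with the age-class
  cancellation probability `p_a` (otherwise the patient attends anyway).
* **Arrival.** Appointment holders arrive with a normal punctuality offset
  (SD 5 min, truncated into the session); walk-ins at a Beta(2,2)-positioned
  instant of the session's open window; same-session retries 30 min after a
  rejection. The admission strategy decides; admitted patients join the
  waiting room (emergency flag cleared), rejected walk-ins take a rating
  penalty, become emergencies, and retry at the next-best untried pair.
* **Treatment complete.** Indicators are recorded; for the first persisting
  illness with more than `ν` of remaining duration, a follow-up appointment
  is requested from the attending practice inside `target ± ν/4`
  (walk-in fallback on failure); after a regular visit the chronic patient
  rebooks with the family physician at `now + ν_ς` (window widened, then
  retried half an interval later, if full); the next waiting patient starts
  service.
* **End of buffer.** One hour after each session close the admission
  threshold learns from the session outcome.

## Strategies (case-study set)

* **Fixed-interval scheduling**: each open session divides into equal slots
  of one patient each; requests get the earliest free slot in the window.
  Library default slot length 10 min; the case-study preset uses 15-min
  slots (see below).
* **Priority FCFS treatment**: appointment holders strictly before walk-ins,
  emergency walk-ins before ordinary ones, first-come-first-served within
  class. Service times are log-normal (CV 0.25) around the base mean,
  scaled by 0.8 while more than 4 patients queue.
* **Priority-threshold admission**: appointment holders are always admitted
  (admitted patients must be treated). A walk-in is admitted iff the
  predicted completion of everyone present plus the session's remaining
  booked slots — `(queue + in service + booked ahead) × current mean
  service time` — stays within the buffer end plus θ; emergencies get
  θ + 30 min. Learning: realized overtime at buffer end lowers θ by 5 min,
  idle time ≥ 10 min raises it by 5 min, bounded to [−60, +60] min.

## Indicators

Collected inside the observation window `[warmup, horizon)` from an
empty-state initialization:

* waiting time: appointment holders from max(arrival, scheduled time) to
  treatment start; walk-ins from arrival. "On time" = treatment starts
  within 5 min of the slot.
* access time: slot time minus the later of request time and due date
  (so a follow-up booked at treatment time for `now + ν` counts the offset
  from its target, not the interval itself), split acute/regular.
* access distance: patient-practice distance per treated visit.
* utilization: service time over published opening hours of the window.
  The post-session buffer is not available time, but work inside it is
  neither idle nor overtime; overtime is work performed after the buffer
  end. Weekly overtime = overtime per physician per 7 window days.
* conservation identities (checked by tests): treatments = attended
  appointments + treated walk-ins; admissions + rejections = arrivals.

Experiments are independent runs summarized by per-KPI means and two-sided
Student-t 95 % confidence intervals.

## Warm-up analysis

Yearly KPI series feed the Schruben–Singh–Tierney initialization-bias test:

    T = √45 · n^(−3/2) · Σ_k (1 − k/n) · k · (Ȳ_n − Ȳ_k) / σ̂

which converges to a standard normal under the no-bias null (the weighted
bridge integral has variance 1/45). σ̂² is the batch-means estimate from 5
batches over the last half of the series, so T is compared two-sidedly
against t with 4 degrees of freedom at α = 0.05. `find_warmup` raises the
truncation in steps (default 5 years) until no tracked KPI rejects.
Monte-Carlo calibration (type-I error ≈ 5 % on i.i.d. series; power against
a decaying −3 SD initial bias at series length 70) runs in the test suite.

## Synthetic scenario generator

The generator rebuilds a rural three-municipality system. Grand totals
follow public census figures for the modeled region: 35 542 residents over
2 754 one-hectare cells, with under-16 counts 1 390 / 2 383 / 1 794
recorded per municipality; the per-municipality resident/cell split, the
cell coordinates (municipality strips of a ~25 × 16 km bounding box), and
the practice locations (near random inhabited cells) are synthetic
stand-ins for confidential geodata. Adult extraction fixes one adult per
cell (children do not live alone) and removes each municipality's child
count uniformly from the remaining residents (multivariate hypergeometric),
leaving exactly 29 975 adults at full scale. Patients then get: a uniform
location within their hectare cell, health `c ~ Beta(25, 25)` (mean 0.5),
an age class from the (0.1196, 0.6318, 0.2486) mix, 14 Bernoulli session
availabilities and a Bernoulli chronic flag with age-specific
probabilities, and — if chronic — a sampled chronic illness. Rosters open
Monday–Friday 8:00–12:00 and 14:00–17:00 with Wednesday afternoons and
weekends closed (32 h/week).

Seven illness families (ICD-10 coded) provide the default tables. The
vaccination family has no natural illness duration; it gets a synthetic
nominal one-day duration so it can flow through the acute machinery as an
episode that resolves immediately and needs no follow-up.

**Preset calibration.** The case-study preset pairs 15-min appointment
slots with a 7-min mean service time. Both derive from the full-scale
reference figures: ~10 000 treatments per physician-year at 72 %
utilization of ~1 630 h implies ≈ 7 min per treatment, while the attended
appointment volume against the slot supply implies slots scarcer than the
service time — pure 10-min slots would leave appointment capacity so slack
that the walk-in channel nearly vanishes. `scale` shrinks the system at a
constant ~1500:1 patients-per-physician ratio; `desk_scenario` (scale
0.15: 3 practices, ~4 500 patients) is the desk-experiment default, chosen
so that a 20-seed scenario comparison completes in minutes. Tests use
150-day horizons with 90-day warm-ups at this scale.

## What the generator does not emulate

Passing tests on synthetic scenarios show internal consistency and the
documented qualitative mechanisms, not forecasts for a real region: real
practice locations cluster in town centers rather than tracking random
cells; opening hours vary by practice; illness traits and the
age-class-illness tables are estimates, not fitted clinical data; and the
short warm-ups of desk-scale tests do not bring the slow rating/family-
physician dynamics to their long-run equilibrium (full-scale analyses use
multi-decade warm-ups).

## Numerical choices and degenerate inputs

Scalar day floats throughout the engine; 1e-9-day tolerances on window and
slot comparisons; ties broken by fixed kind priority, then insertion
sequence, then lexicographic identifiers. Zero-variance configurations
collapse samplers onto their means (log-normal/Weibull with zero mean or
dispersion return the mean; triangular returns its mode). Empty waiting
rooms are a programming error for treatment strategies; empty scenarios
fail validation (which reports *all* violations), though the engine itself
produces all-zero indicators on a patient-free system. Appointments freed
by cancellation release their slot; stale arrival events for cancelled
bookings are skipped lazily.

## Known limitations

Strategy parameters beyond the main text of the underlying design are
package choices exposed in configuration, not fitted values. Overtime work
is attributed to the session in which the treatment started, which slightly
misattributes spillover across a session boundary under extreme overload.
Walk-in retries within a session use a fixed 30-min travel delay rather
than a travel-time submodel. Batch-means single-run experimentation is out
of scope (independent runs only).
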