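# Methods

## The clinic-day model

One provider serves a session of `m` equally long slots (duration `d`,
default 30 minutes; default session 9:00 onward). An assignment books each
rostered patient into exactly one slot, at most `capacity` (default 2) per
slot, with a within-slot service priority. Patients show independently
with probability `p_i`; shown patients arrive punctually at their slot
start and are served, in (slot, priority) order, for exactly `d` minutes.
A patient's wait is service start minus slot start; no-shows wait zero and
consume no provider time. Idle time and overtime follow from the
accounting identities

```
idle     = max(session_end, last_completion) − session_start − d · n_shown
overtime = max(0, last_completion − session_end)
```

All times are integer minutes from session start, so the recursion is
exact. Two modelling assumptions are deliberate and load-bearing:
**deterministic service equal to the slot length** (the worked-example
arithmetic, and the backlog-chain evaluation below, both rely on it) and
**punctual arrivals** (lateness is folded into no-show behaviour).
Stochastic service times, walk-ins, cancellations, heterogeneous slot
lengths and multi-provider clinics are out of scope.

Within-slot priority is roster order everywhere the optimizers are
involved. This is a fairness guarantee as much as a convention: who is
served first among double-booked patients must not depend on group
membership, and fixing it also makes the enumeration oracle and the local
search explore the same space (priority is otherwise a free variable the
fairness objectives could exploit).

A slot is **undesirable** iff it holds two or more patients or directly
follows such a slot; patients inherit their slot's label. Quota
constraints are expressed over desirable slots.

## Expected outcomes: three routes

1. **Enumeration** (`expected_outcome_exact`): all `2^n` show vectors,
   each weighted by `Π p^s (1−p)^(1−s)`; vectorized over scenarios; capped
   at n = 20 (~10^6 scenarios).
2. **Backlog chain** (`BacklogEvaluator`): with unit service times the
   provider state at slot k collapses to an integer backlog
   `b_k = (max(free, slot start) − slot start)/d`, which evolves as
   `b_{k+1} = max(0, b_k + m_k − 1)` with `m_k` the slot's shown count.
   The priority-r patient of slot k waits `d · (b_k + shown ahead in
   slot)` when present, overtime is `d ·` final backlog, and idle follows
   from the conservation identity. Propagating the exact distribution of
   `b_k` gives the same expectations as enumeration (tested to 1e-9) at
   cost linear in the number of slots — this is what the optimizer's
   inner loop evaluates, and it has no roster-size cap.
3. **Monte-Carlo** (`expected_outcome_mc`): seeded Bernoulli sampling with
   per-aggregate standard errors, for anything the enumeration cap
   excludes and for cross-checks.

Schedule cost is `w_wait·ΣE[wait] + w_idle·E[idle] + w_ot·E[overtime]`;
weights default to (1, 1, 1) and are configurable — every cost-level
comparison in this package is therefore weight-relative, and "schedule
quality" is reported only as the negation of cost.

## Show-probability models

Three regimes of a plain, unpenalized logistic regression:

* **FULL** — socio-economic features plus two attendance-history
  summaries (`past_show_count`, `past_visit_count`);
* **NO_SES** — history summaries only;
* **NONE** — no model; every patient receives the history's overall show
  rate.

Training rows are individual past visits. The history summary attached to
a row is computed **leave-one-out** (from the patient's other visits), so
an outcome never summarizes itself; with the SES features present the
summary is then conditionally independent of the outcome, which is why a
FULL refit recovers the generator's coefficients. Zero-variance training
columns (e.g. `past_visit_count` when all patients share one history
length) are dropped and recorded on the model. Calendar features are
accepted if present in a roster but not required.

## Synthetic population

The generator emulates the asserted structure of US outpatient no-show
data: a binary group label (minority "B", 30% of patients) shifts three
socio-economic features — income index N(−0.5, 1) vs N(0.5, 1),
employment 0.60 vs 0.85, marriage 0.45 vs 0.55 — and the latent show
probability is `logistic(0.9 + 1.0·income + 0.8·employed + 0.3·married)`.
The group label never enters that equation: any downstream group
difference is proxy-mediated by construction, and a logistic refit with
the group label added finds a coefficient statistically indistinguishable
from zero (tested). The implied group mean show rates are ≈ 0.87 vs
≈ 0.71 (Gauss–Hermite quadrature, cross-checked by simulation) — a margin
of ≈ 0.15.

Histories are independent Bernoulli draws from the latent probability,
**6 visits per patient** by default. The length matters: history
summaries are the only group-correlated signal available to the NO_SES
model, and a handful of visits (typical of outpatient rosters) makes them
a *noisy* proxy — informative enough that NO_SES retains real disparity,
noisy enough that it loses prediction quality relative to FULL. Very long
histories would make the past show rate nearly as informative as the
socio-economic features themselves and erase the contrast between the
two prediction-side interventions.

What the generator does **not** emulate: calendar/seasonal structure,
serially correlated attendance, covariate shift between training and
scheduling populations, measurement error in features, and any direct
group effect on attendance. Passing benchmarks here therefore demonstrate
the mechanics of proxy-mediated disparity and its repair under clean
conditions, not effect sizes for any real clinic.

## Objectives and optimizers

All variants share the idle and overtime cost terms and differ in the
wait term:

* **TRADITIONAL** — total expected wait (efficiency only; never reads
  group labels).
* **RACE_UNAWARE** — `n · max_i E[wait_i]`: protect whoever is expected
  to wait longest, blind to groups. The max uses the unconditional
  expected wait — the schedule's exposure for that patient, attendance
  uncertainty included — and is scaled by `n` for unit comparability.
* **RACE_AWARE** — total expected wait plus
  `0.5 · n · (max_g w̄_g − min_g w̄_g)`, where `w̄_g` is the group's mean
  wait *conditional on attendance* (the same quantity the disparity
  metric reports). Whenever one group is expected to wait longer the
  optimizer is rewarded for shrinking that group's wait, and exact group
  equality is the penalty's minimum.

The race-aware composition deserves its history. Two simpler forms were
implemented and measured first. A max over *unconditional* group means
lets the optimizer discount a low-attendance group's waits by their own
no-show rate, so booking the minority into bad slots can read as fair. A
min-max over *conditional* group means (with or without a tie-breaking
spread penalty) is flat in every move once the protected group's mean
falls below the other's; a discrete search therefore stalls past the
crossing, and because a patient-minute placed on a ~3.6-patient group
moves its mean about 2.3× as much as the majority's, the stall is
systematically on the over-protective side — measured at −10 % to −24 %
pooled disparity, a *reverse* inequity the method is not supposed to
create. The efficiency-plus-spread form has no flat region, equality is
the penalty's unique minimum, and the efficiency term pulls from the
positive side, so realized disparity centres near zero. The spread weight
(`RACE_AWARE_BALANCE = 0.5` patient-minutes per minute of group gap) sets
the exchange rate between efficiency and equalization.

Two solvers:

* **Enumeration oracle** (`optimize_oracle`, n ≤ 7, m ≤ 5): every
  capacity-feasible slot membership, canonical priority, constraint
  filtering, lexicographic tie-break on the (slot per patient) encoding —
  group-blind by construction. The correctness reference.
* **Iterated local search** (`optimize_heuristic`): deterministic greedy
  start (reliable patients one per slot, stragglers overbook the earliest
  slots) plus seeded random restarts; best-improvement descent over
  single-patient moves and pairwise swaps; seeded multi-step kicks with
  re-descent, improvements kept. Returned assignments always satisfy the
  active quotas (an infeasible start is first repaired by descending on
  total quota shortfall), and never score worse than a feasible greedy
  start. Defaults (3 starts, 15 kicks) match the oracle on all tested
  enumerable instances; the benchmark runs a lighter budget (1 start,
  5 kicks) as a throughput choice.

Quota constraints: `GROUP_QUOTA` (minimum fraction of desirable slots per
group) and `RISK_QUOTA` (minimum fraction for the highest no-show-risk
tercile, i.e. the `ceil(n/3)` lowest predicted show probabilities, ties
by patient id). When no slot is desirable the fractions are undefined and
the constraint reports unsatisfied. Statistical parity is exposed as a
metric only, not as a hard constraint.

## Fairness metrics

Group mean waits are **conditional on attendance**: `Σ E[wait] / Σ p`
within the group. The unconditional alternative scales each patient's
wait by their own show probability, which makes a group-blind scheduler
look *anti*-disparate simply because the minority group attends less;
conditioning removes exactly that artifact (tested). Disparity is the
percent difference of the two group means over their average — a
symmetric denominator that stays stable when one mean approaches zero;
the non-protected group's mean and the overall mean are available
alternatives. Signs are reported as computed; positive means the
protected group waits longer. The statistical-parity gap is
`P(wait > t | group, shown)` differenced across groups, exact within the
enumeration cap, with threshold t = 0 (any wait) by default. The
optimality gap is `100 · (cost − cost_ref)/cost_ref`.

## The benchmark

`run_comparison` fits one model per regime on a 2 000-patient training
population, then replicates clinic days: fresh 12-patient roster (drawn
until both groups are present — disparity is undefined otherwise), 10
slots, capacity 2, so two double-bookings are forced. Each method
optimizes on its own predictions and is scored under the latent true
probabilities; optimality gaps are day-matched against SOTA. Disparity is
**pooled** — group wait and expected-show sums accumulated over all days,
one ratio at the end, delete-one-day jackknife for the standard error —
because a per-day percent ratio over ~3.6 minority patients is dominated
by small-sample noise (days where no minority patient is delayed clamp
the ratio at −200 %). Per-day values are retained in the output for
inspection. Every random stage (training draw, day rosters, optimizer
seeds) derives from the single master seed.

Problem sizes (200 days, 12 patients, 2 000 training patients) are chosen
so a full five-method comparison, evaluated exactly, completes in about
three minutes on one core. With these defaults the comparison reproduces
the qualitative pattern the decoupling argument predicts: disparity
SOTA > NO_SES > RACE_UNAWARE > RACE_AWARE ≈ 0 ≈ NO_ML, and efficiency
loss RACE_AWARE < NO_SES < RACE_UNAWARE < NO_ML. One divergence from the
original study's scale is expected and known: here the race-unaware
min-max objective costs far more efficiency than the NO_SES intervention
(its n-scaled max term dominates the cost terms at this day size),
whereas the two were comparable in the original data.

## Numerical and degenerate-input conventions

* Exact enumeration refuses n > 20 and points to Monte-Carlo; the backlog
  chain has no cap and is float-exact to ~1e-12 of enumeration.
* Optimizer improvement threshold 1e-9 (also the quota slack); oracle
  ties resolve to the lexicographically first encoding encountered.
* Generator configurations whose latent probabilities round to exactly 0
  or 1 in floating point are rejected.
* Disparity with both group means zero is 0 by convention; an empty group
  raises a metric-undefined error rather than returning a number.
* A degenerate history (all shows or all no-shows) is a fit error for the
  logistic regimes; NONE still works wherever the history is nonempty.
* `master_seed` feeds `numpy.random.default_rng`; derived seeds are drawn
  below 2^31.

## Known limitations

* Capacity is effectively "double-booking" in spirit; higher capacities
  are accepted but untested against any narrative arithmetic.
* The race-aware spread weight 0.5 is a declared default, not an
  estimate; the right exchange rate for a real clinic depends on the cost
  weights, which the literature does not publish.
* The heuristic has no optimality certificate beyond oracle agreement on
  enumerable instances; an integer-programming backend would provide one
  but is not required for the problem sizes studied here.
* Percent disparities on small synthetic days are large in magnitude
  (the denominator is a few minutes of mean wait); only orderings and
  signs, not magnitudes, transfer to other settings.
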