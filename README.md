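# fairbook

Fair predictive overbooking for outpatient appointment scheduling.

Clinics hedge against patient no-shows by double-booking appointment
slots. State-of-the-art schedulers do this *predictively*: a machine-learning
model estimates each patient's show probability, and an optimizer books the
least reliable patients into overbooked slots (or the slot right after one),
because that minimizes expected schedule cost. In US clinic data, show
probability correlates with socio-economic features that in turn correlate
with race, so this efficient policy concentrates the long waits on Black
patients. `fairbook` implements the scheduling pipeline with the prediction
and optimization stages *decoupled*, so each can be intervened on
independently, and measures what every intervention costs and repairs:

* **prediction interventions** — drop the model entirely (every patient gets
  the population show rate), or refit it without socio-economic features;
* **optimization interventions** — replace the efficiency objective with a
  race-aware objective (equalize the two groups' mean waits) or a
  race-unaware one (minimize the longest individual expected wait), or add
  quota constraints reserving a share of desirable slots for a group or for
  the highest no-show-risk tercile.

It is written for operations-research and algorithmic-fairness researchers
who want a small, exactly evaluable testbed rather than a production
scheduler.

## The model

A session has `m` slots of fixed length `d` (default 30 min) served by one
provider; up to two patients share a slot. Patient `i` shows independently
with probability `p_i`, arrives punctually, and service takes exactly `d`.
Serving shown patients in (slot, priority) order gives each one a wait of
`max(0, provider free time − slot start)`; the session's **schedule cost** is

```
cost = w_wait · Σ_i E[wait_i] + w_idle · E[idle] + w_overtime · E[overtime]
```

with expectations over the `2^n` show vectors — computed exactly, either by
direct enumeration or by an equivalent backlog Markov chain that scales to
any roster size. A slot is **undesirable** if it is overbooked or
immediately follows an overbooked slot. Fairness is measured as the percent
difference between the groups' mean waits conditional on attendance,

```
disparity = 100 · (w̄_B − w̄_nonB) / mean(w̄_B, w̄_nonB),
```

as the statistical-parity gap `P(wait > t | B, shown) − P(wait > t | nonB,
shown)`, and as the optimality gap of a method's cost against the
cost-minimizing scheduler on the same instance.

## Worked example

The packaged five-patient day books `a` alone at 9:00, double-books `d` and
`e` at 9:30 (`d` served first), and gives `c` and `b` the 10:00 and 10:30
slots. With every patient forced to show (`show_prob = 1`):

```bash
fairbook evaluate -c config.yaml \
    --roster roster_all_show.csv \
    --assignment demo_assignment.csv -o out/
```

```
expected wait a: 0.0 min
expected wait b: 30.0 min
expected wait c: 30.0 min
expected wait d: 0.0 min
expected wait e: 30.0 min
schedule cost 120.00  disparity +28.6%
```

`e` waits 30 minutes behind `d`; the backlog delays `c`, and with all five
present it reaches `b` too. Under the patients' actual show probabilities
(0.90 for `a`/`b`, 0.45/0.40/0.35 for `c`/`d`/`e`) the same assignment gives

```
expected wait e: 4.2 min      # 0.35 · 0.40 · 30
expected wait c: 1.9 min
expected wait b: 1.7 min
schedule cost 41.19  disparity +137.2%
```

— efficient in expectation, but the entire waiting burden sits on the group
with the lower show rates: that asymmetry is the problem this package
studies.

## Five methods, one benchmark

`fairbook compare` replicates clinic days from a synthetic population in
which group membership shifts income, employment and marital status, and
show probability depends on those features only (never on the group label
itself). Five methods are compared on the same days: `SOTA` (full model +
efficiency objective), `NO_ML`, `NO_SES`, `RACE_AWARE`, `RACE_UNAWARE`.
Schedules are optimized on each method's *predictions* but scored under the
*latent true* probabilities, so prediction quality surfaces as realized
cost:

```bash
fairbook compare -c src/fairbook/data/example_config.yaml -o out/
```

On the default configuration (200 days, 12 patients into 10 slots, master
seed 0) this prints, in ~3 minutes:

```
method comparison (mean ± MC standard error over days)

SOTA           optimality gap     0.00 ±  0.00 %   disparity    93.61 ±  6.82 %
NO_ML          optimality gap    74.85 ±  3.41 %   disparity     3.90 ±  8.57 %
NO_SES         optimality gap    15.87 ±  1.00 %   disparity    68.03 ±  7.64 %
RACE_AWARE     optimality gap     7.31 ±  0.62 %   disparity    -5.46 ±  2.13 %
RACE_UNAWARE   optimality gap    65.33 ±  2.01 %   disparity     5.80 ±  2.84 %
```

The qualitative picture: removing the model removes the disparity but is
very expensive; removing only socio-economic features recovers most of the
efficiency but keeps most of the disparity (attendance history is itself a
group-correlated proxy); intervening on the *objective* instead — the
race-aware method — removes the disparity at the smallest efficiency price.
Magnitudes are properties of the synthetic population and the small day
size; the ordering is the finding.

## Layout

| module | contents |
|---|---|
| `fairbook.core` | patients, slot grids, assignments, the clinic-day recursion, slot desirability |
| `fairbook.synth` | synthetic populations and attendance histories |
| `fairbook.models` | show-probability models (FULL / NO_SES / NONE regimes) |
| `fairbook.evaluate` | exact, backlog-chain and Monte-Carlo expected outcomes; schedule cost |
| `fairbook.optimize` | objective variants, quota constraints, enumeration oracle, iterated local search |
| `fairbook.metrics` | wait disparity, statistical parity, optimality gap |
| `fairbook.bench` | the replicated-day comparison harness |
| `fairbook.cli` | `fairbook simulate / fit / schedule / evaluate / compare` |

Design notes, parameter choices and known limitations are in
[docs/methods.md](docs/methods.md).
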