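"""Slot-assignment optimization under four objective/constraint regimes.

Three objective variants share the idle and overtime terms of the
schedule cost and differ in the wait term:

* TRADITIONAL minimizes total expected wait (the efficiency-only,
  state-of-the-art objective);
* RACE_AWARE keeps the total-wait term and adds n * (the spread
  between the groups' attendance-conditional mean waits): whenever one
  group is expected to wait longer, the optimizer is rewarded for
  shrinking that group's wait, with exact group equality as the
  penalty's minimum — this is the only variant allowed to read group
  labels;
* RACE_UNAWARE replaces it with n * (the largest individual expected
  wait), helping whoever waits longest without touching group labels.

The race-unaware max term is scaled by the roster size so the three
wait terms share patient-minute units; when every patient's expected
wait is equal, all three variants coincide.

Optional quota constraints restrict the share of desirable slots: a
GROUP_QUOTA demands a minimum fraction per group, a RISK_QUOTA reserves
a minimum fraction for patients whose no-show risk is in the highest
third of the roster.

Two solvers are provided: an exhaustive-enumeration oracle for tiny
instances (the correctness reference) and a seeded multi-start local
search over single-patient moves and pairwise swaps for realistic sizes.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np

from .core import Assignment, Desirability, Roster, SlotGrid, classify_slots
from .errors import (
    ConfigurationError,
    InfeasibleError,
    InvalidAssignmentError,
    SizeLimitError,
)
from .evaluate import BacklogEvaluator, CostWeights, DayEvaluator

_TOL = 1e-9

#: Weight of the group-wait-spread penalty in the race-aware wait term,
#: relative to a patient-minute of total wait.  The race-aware
#: objective keeps the full efficiency objective and adds
#: balance * n * (max group mean wait - min group mean wait): whenever
#: one group waits longer, reducing that group's wait is rewarded, and
#: exact equality is the penalty's minimum.  A pure min-max (or
#: max-plus-spread) group term was tried first and systematically
#: over-protects the smaller group into *reverse* disparity, because a
#: patient-minute moved onto a small group raises its mean far more
#: than the same minute raises a large group's.
RACE_AWARE_BALANCE = 0.5


class ObjectiveVariant(str, enum.Enum):
    TRADITIONAL = "TRADITIONAL"
    RACE_AWARE = "RACE_AWARE"
    RACE_UNAWARE = "RACE_UNAWARE"


class QuotaKind(str, enum.Enum):
    GROUP_QUOTA = "GROUP_QUOTA"
    RISK_QUOTA = "RISK_QUOTA"


@dataclass(frozen=True)
class QuotaConstraint:
    """A minimum share of desirable slots.

    GROUP_QUOTA: ``minima`` maps group label -> minimum fraction of
    desirable slots that must be held by that group.  RISK_QUOTA:
    ``min_fraction`` of desirable slots must be held by patients whose
    predicted show probability is in the lowest third of the roster
    (i.e. the highest no-show risk tercile).
    """

    kind: QuotaKind
    minima: Mapping[str, float] | None = None
    min_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind == QuotaKind.GROUP_QUOTA:
            if not self.minima:
                raise ConfigurationError("GROUP_QUOTA requires per-group minima")
            for g, f in self.minima.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(f"quota for group {g!r} outside [0, 1]")
        else:
            if self.min_fraction is None or not 0.0 <= self.min_fraction <= 1.0:
                raise ConfigurationError("RISK_QUOTA requires min_fraction in [0, 1]")

    @classmethod
    def group_quota(cls, minima: Mapping[str, float]) -> "QuotaConstraint":
        return cls(QuotaKind.GROUP_QUOTA, minima=dict(minima))

    @classmethod
    def risk_quota(cls, min_fraction: float) -> "QuotaConstraint":
        return cls(QuotaKind.RISK_QUOTA, min_fraction=min_fraction)


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective variant, cost weights, and optional quota constraints."""

    variant: ObjectiveVariant = ObjectiveVariant.TRADITIONAL
    weights: CostWeights = field(default_factory=CostWeights)
    constraints: tuple[QuotaConstraint, ...] = ()


@dataclass(frozen=True)
class QuotaResult:
    satisfied: bool
    attained: dict[str, float]
    minima: dict[str, float]
    n_desirable: int


def risk_tercile_ids(show_probs: Mapping[str, float]) -> frozenset[str]:
    """Patients whose no-show risk is in the highest third: the
    ceil(n/3) lowest show probabilities, boundary ties broken by
    patient_id order."""
    n = len(show_probs)
    k = math.ceil(n / 3)
    ranked = sorted(show_probs, key=lambda pid: (show_probs[pid], pid))
    return frozenset(ranked[:k])


def check_quota(
    assignment: Assignment,
    grid: SlotGrid,
    roster: Roster,
    constraint: QuotaConstraint,
    show_probs: Mapping[str, float] | None = None,
) -> QuotaResult:
    """Fraction of desirable slots held by each protected category, and
    whether every minimum is met.

    Desirable slots hold at most one patient (an overbooked slot is by
    definition undesirable); an empty desirable slot counts in the
    denominator but toward no group.  When no slot is desirable the
    fractions are undefined (NaN) and the constraint is unsatisfied.
    """
    labels = classify_slots(assignment, grid)
    desirable = [i for i, lab in enumerate(labels) if lab is Desirability.DESIRABLE]
    n_des = len(desirable)
    groups = roster.groups()
    if constraint.kind == QuotaKind.GROUP_QUOTA:
        minima = dict(constraint.minima or {})
        counts = dict.fromkeys(minima, 0)
        for i in desirable:
            for pid in assignment.slots[i]:
                g = groups[pid]
                if g in counts:
                    counts[g] += 1
        if n_des == 0:
            attained = {g: float("nan") for g in minima}
            return QuotaResult(False, attained, minima, 0)
        attained = {g: counts[g] / n_des for g in minima}
        ok = all(attained[g] >= minima[g] - _TOL for g in minima)
        return QuotaResult(ok, attained, minima, n_des)
    # RISK_QUOTA
    if show_probs is None:
        show_probs = roster.show_probs()
    top_risk = risk_tercile_ids(show_probs)
    minima = {"top_risk_tercile": float(constraint.min_fraction)}  # type: ignore[arg-type]
    if n_des == 0:
        return QuotaResult(False, {"top_risk_tercile": float("nan")}, minima, 0)
    count = sum(
        1 for i in desirable for pid in assignment.slots[i] if pid in top_risk
    )
    attained = {"top_risk_tercile": count / n_des}
    ok = attained["top_risk_tercile"] >= minima["top_risk_tercile"] - _TOL
    return QuotaResult(ok, attained, minima, n_des)


def _satisfies_all(
    assignment: Assignment,
    grid: SlotGrid,
    roster: Roster,
    spec: ObjectiveSpec,
    show_probs: Mapping[str, float],
) -> bool:
    return all(
        check_quota(assignment, grid, roster, c, show_probs).satisfied
        for c in spec.constraints
    )


def _wait_term(
    expected_wait: Mapping[str, float],
    show_probs: Mapping[str, float],
    variant: ObjectiveVariant,
    groups: Mapping[str, str] | None,
) -> float:
    """Wait component of the objective, in patient-minutes.

    RACE_AWARE keeps the total-wait efficiency term and adds a penalty
    on the spread between group mean waits *conditional on attendance*
    — the same quantity the disparity metric reports (an unconditional
    group mean would reward booking a low-attendance group into bad
    slots, since their waits are discounted by their own show
    probability).  Whenever one group is expected to wait longer,
    shrinking that group's wait shrinks the term, and group equality is
    its minimum.  RACE_UNAWARE targets the largest individual
    (unconditional) expected wait: the patient expected to wait
    longest, attendance uncertainty included.
    """
    n = len(expected_wait)
    if variant == ObjectiveVariant.TRADITIONAL:
        return float(sum(expected_wait.values()))
    if variant == ObjectiveVariant.RACE_UNAWARE:
        return n * max(expected_wait.values())
    if groups is None:
        raise ConfigurationError("RACE_AWARE objective requires group labels")
    wait_sum: dict[str, float] = {}
    prob_sum: dict[str, float] = {}
    for pid, w in expected_wait.items():
        g = groups[pid]
        wait_sum[g] = wait_sum.get(g, 0.0) + w
        prob_sum[g] = prob_sum.get(g, 0.0) + show_probs[pid]
    means = [
        (wait_sum[g] / prob_sum[g] if prob_sum[g] > 0 else 0.0) for g in wait_sum
    ]
    total = float(sum(expected_wait.values()))
    return total + RACE_AWARE_BALANCE * n * (max(means) - min(means))


def objective_value(
    assignment: Assignment,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    roster: Roster | None,
    spec: ObjectiveSpec,
    evaluator: DayEvaluator | BacklogEvaluator | None = None,
) -> float:
    """Value of the chosen objective for one assignment.

    TRADITIONAL and RACE_UNAWARE never touch group labels; RACE_AWARE
    reads them from ``roster`` and errors without one.  The default
    evaluator is the exact backlog chain (any roster size).
    """
    if evaluator is None:
        evaluator = BacklogEvaluator(grid, show_probs)
    outcome = evaluator.outcome(assignment)
    groups = None
    if spec.variant == ObjectiveVariant.RACE_AWARE:
        if roster is None:
            raise ConfigurationError("RACE_AWARE objective requires a roster with groups")
        groups = roster.groups()
    w = spec.weights
    return (
        w.w_wait * _wait_term(outcome.expected_wait, show_probs, spec.variant, groups)
        + w.w_idle * outcome.expected_idle
        + w.w_overtime * outcome.expected_overtime
    )


def _objective_fn(
    grid: SlotGrid,
    roster: Roster | None,
    spec: ObjectiveSpec,
    evaluator: DayEvaluator | BacklogEvaluator,
):
    groups = None
    if spec.variant == ObjectiveVariant.RACE_AWARE:
        if roster is None:
            raise ConfigurationError("RACE_AWARE objective requires a roster with groups")
        groups = roster.groups()
    w = spec.weights

    def value(assignment: Assignment) -> float:
        outcome = evaluator.outcome(assignment)
        return (
            w.w_wait
            * _wait_term(outcome.expected_wait, evaluator.probs, spec.variant, groups)
            + w.w_idle * outcome.expected_idle
            + w.w_overtime * outcome.expected_overtime
        )

    return value


def optimize_oracle(
    roster: Roster,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    spec: ObjectiveSpec,
    max_patients: int = 7,
    max_slots: int = 5,
) -> Assignment:
    """Exhaustively enumerate every capacity-feasible assignment and
    return the constraint-feasible minimizer.

    Within-slot priority is canonicalized to roster order.  Ties are
    broken lexicographically on the (slot index per patient, in roster
    order) encoding, which is group-blind; enumeration proceeds in that
    order and only strict improvements replace the incumbent.
    """
    pids = roster.ids
    n, m = len(pids), grid.n_slots
    if n > max_patients or m > max_slots:
        raise SizeLimitError(
            f"oracle limited to {max_patients} patients x {max_slots} slots; "
            f"got {n} x {m} — use optimize_heuristic"
        )
    if n > m * grid.capacity:
        raise InvalidAssignmentError(
            f"{n} patients cannot fit {m} slots of capacity {grid.capacity}"
        )
    evaluator = BacklogEvaluator(grid, show_probs)
    value = _objective_fn(grid, roster, spec, evaluator)
    best: Assignment | None = None
    best_val = math.inf
    never_satisfied = [True] * len(spec.constraints)
    for combo in itertools.product(range(1, m + 1), repeat=n):
        counts = [0] * m
        ok = True
        for s in combo:
            counts[s - 1] += 1
            if counts[s - 1] > grid.capacity:
                ok = False
                break
        if not ok:
            continue
        buckets: list[list[str]] = [[] for _ in range(m)]
        for pid, s in zip(pids, combo):
            buckets[s - 1].append(pid)
        assignment = Assignment(tuple(tuple(b) for b in buckets))
        feasible = True
        for ci, c in enumerate(spec.constraints):
            if check_quota(assignment, grid, roster, c, show_probs).satisfied:
                never_satisfied[ci] = False
            else:
                feasible = False
        if not feasible:
            continue
        v = value(assignment)
        if v < best_val - _TOL:
            best, best_val = assignment, v
    if best is None:
        binding = [
            spec.constraints[i].kind.value
            for i, flag in enumerate(never_satisfied)
            if flag
        ] or [c.kind.value for c in spec.constraints]
        raise InfeasibleError(
            f"no capacity-feasible assignment satisfies the quota constraints "
            f"(binding: {', '.join(binding)})"
        )
    return best


def _canonical(buckets: list[list[str]], pos: Mapping[str, int]) -> Assignment:
    """Fix within-slot priority to roster order (group-blind by
    construction); the optimizers search over slot memberships only."""
    return Assignment(
        tuple(tuple(sorted(b, key=lambda pid: pos[pid])) for b in buckets)
    )


def _greedy_initial(
    roster: Roster, grid: SlotGrid, show_probs: Mapping[str, float]
) -> Assignment:
    """Deterministic constructive start: the highest-show-probability
    patients take one slot each in slot order; leftover (lowest
    probability) patients overbook the earliest slots with room."""
    pids = sorted(roster.ids, key=lambda pid: (-show_probs[pid], pid))
    m = grid.n_slots
    if len(pids) > m * grid.capacity:
        raise InvalidAssignmentError(
            f"{len(pids)} patients cannot fit {m} slots of capacity {grid.capacity}"
        )
    buckets: list[list[str]] = [[] for _ in range(m)]
    for i, pid in enumerate(pids[:m]):
        buckets[i].append(pid)
    for pid in pids[m:]:
        for b in buckets:
            if len(b) < grid.capacity:
                b.append(pid)
                break
    pos = {pid: i for i, pid in enumerate(roster.ids)}
    return _canonical(buckets, pos)


def _random_assignment(
    roster: Roster, grid: SlotGrid, rng: np.random.Generator
) -> Assignment:
    pids = list(roster.ids)
    rng.shuffle(pids)
    buckets: list[list[str]] = [[] for _ in range(grid.n_slots)]
    slot_cycle = itertools.cycle(range(grid.n_slots))
    for pid in pids:
        for _ in range(grid.n_slots):
            s = next(slot_cycle)
            if len(buckets[s]) < grid.capacity:
                buckets[s].append(pid)
                break
    pos = {pid: i for i, pid in enumerate(roster.ids)}
    return _canonical(buckets, pos)


def _neighbors(assignment: Assignment, capacity: int, pos: Mapping[str, int]):
    """Single-patient moves and pairwise cross-slot swaps, in a
    deterministic order, with canonical within-slot priority."""
    slots = [list(s) for s in assignment.slots]
    m = len(slots)
    for i in range(m):
        for k in range(len(slots[i])):
            for j in range(m):
                if j == i or len(slots[j]) >= capacity:
                    continue
                new = [list(s) for s in slots]
                pid = new[i].pop(k)
                new[j].append(pid)
                yield _canonical(new, pos)
    for i in range(m):
        for j in range(i + 1, m):
            for k in range(len(slots[i])):
                for l in range(len(slots[j])):
                    new = [list(s) for s in slots]
                    new[i][k], new[j][l] = new[j][l], new[i][k]
                    yield _canonical(new, pos)


def _local_search(
    start: Assignment,
    grid: SlotGrid,
    roster: Roster,
    spec: ObjectiveSpec,
    show_probs: Mapping[str, float],
    value,
    max_iters: int,
) -> tuple[Assignment, float]:
    """Best-improvement hill climbing over feasible neighbors."""
    pos = {pid: i for i, pid in enumerate(roster.ids)}
    cur, cur_val = start, value(start)
    for _ in range(max_iters):
        best_nb, best_val = None, cur_val
        for nb in _neighbors(cur, grid.capacity, pos):
            if spec.constraints and not _satisfies_all(nb, grid, roster, spec, show_probs):
                continue
            v = value(nb)
            if v < best_val - _TOL:
                best_nb, best_val = nb, v
        if best_nb is None:
            break
        cur, cur_val = best_nb, best_val
    return cur, cur_val


def _perturb(
    assignment: Assignment,
    grid: SlotGrid,
    pos: Mapping[str, int],
    rng: np.random.Generator,
    kick_size: int,
) -> Assignment:
    """Apply a few random moves/swaps to escape a local optimum."""
    slots = [list(s) for s in assignment.slots]
    m = len(slots)
    for _ in range(kick_size):
        occupied = [(i, k) for i in range(m) for k in range(len(slots[i]))]
        i, k = occupied[int(rng.integers(len(occupied)))]
        if rng.random() < 0.5:
            room = [j for j in range(m) if j != i and len(slots[j]) < grid.capacity]
            if room:
                j = room[int(rng.integers(len(room)))]
                slots[j].append(slots[i].pop(k))
                continue
        others = [(j, l) for j, l in occupied if j != i]
        if others:
            j, l = others[int(rng.integers(len(others)))]
            slots[i][k], slots[j][l] = slots[j][l], slots[i][k]
    return _canonical(slots, pos)


def _repair_feasible(
    start: Assignment,
    grid: SlotGrid,
    roster: Roster,
    spec: ObjectiveSpec,
    show_probs: Mapping[str, float],
    max_iters: int = 50,
) -> Assignment | None:
    """Hill-climb on total quota shortfall until feasible; None on failure."""

    def shortfall(a: Assignment) -> float:
        total = 0.0
        for c in spec.constraints:
            res = check_quota(a, grid, roster, c, show_probs)
            for g, minimum in res.minima.items():
                att = res.attained[g]
                if math.isnan(att):
                    total += minimum + 1.0
                else:
                    total += max(0.0, minimum - att)
        return total

    pos = {pid: i for i, pid in enumerate(roster.ids)}
    cur, cur_sf = start, shortfall(start)
    for _ in range(max_iters):
        if cur_sf <= _TOL:
            return cur
        best_nb, best_sf = None, cur_sf
        for nb in _neighbors(cur, grid.capacity, pos):
            sf = shortfall(nb)
            if sf < best_sf - _TOL:
                best_nb, best_sf = nb, sf
        if best_nb is None:
            return None
        cur, cur_sf = best_nb, best_sf
    return cur if cur_sf <= _TOL else None


def optimize_heuristic(
    roster: Roster,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    spec: ObjectiveSpec,
    seed: int = 0,
    n_starts: int = 3,
    max_iters: int = 100,
    n_kicks: int = 15,
    kick_size: int = 3,
) -> Assignment:
    """Seeded iterated local search over moves and swaps.

    The first start is a deterministic greedy assignment; further starts
    are seeded random assignments.  Each start is improved by
    best-improvement descent, then ``n_kicks`` rounds of a random
    ``kick_size``-step perturbation followed by re-descent (improvements
    kept).  The returned assignment satisfies every quota constraint and
    its objective never exceeds that of the (feasible) greedy start.
    With ``max_iters=0`` the greedy start is returned untouched (after a
    feasibility check).
    """
    evaluator = BacklogEvaluator(grid, show_probs)
    value = _objective_fn(grid, roster, spec, evaluator)
    rng = np.random.default_rng(seed)
    greedy = _greedy_initial(roster, grid, show_probs)
    if max_iters == 0:
        if spec.constraints and not _satisfies_all(greedy, grid, roster, spec, show_probs):
            raise InfeasibleError(
                "greedy start violates a quota constraint and no repair "
                "iterations were allowed"
            )
        return greedy
    starts = [greedy] + [
        _random_assignment(roster, grid, rng) for _ in range(max(0, n_starts - 1))
    ]
    pos = {pid: i for i, pid in enumerate(roster.ids)}
    best: Assignment | None = None
    best_val = math.inf
    for start in starts:
        cand: Assignment | None = start
        if spec.constraints and not _satisfies_all(start, grid, roster, spec, show_probs):
            cand = _repair_feasible(start, grid, roster, spec, show_probs)
        if cand is None:
            continue
        cur, cur_val = _local_search(
            cand, grid, roster, spec, show_probs, value, max_iters
        )
        for _ in range(n_kicks):
            kicked = _perturb(cur, grid, pos, rng, kick_size)
            if spec.constraints and not _satisfies_all(
                kicked, grid, roster, spec, show_probs
            ):
                continue
            trial, trial_val = _local_search(
                kicked, grid, roster, spec, show_probs, value, max_iters
            )
            if trial_val < cur_val - _TOL:
                cur, cur_val = trial, trial_val
        if cur_val < best_val - _TOL:
            best, best_val = cur, cur_val
    if best is None:
        binding = ", ".join(c.kind.value for c in spec.constraints)
        raise InfeasibleError(
            f"local search found no assignment satisfying the quota "
            f"constraints (binding: {binding})"
        )
    return best
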