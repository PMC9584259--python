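"""Expected-outcome evaluation and schedule cost.

The schedule cost of an assignment is the weighted sum of total expected
patient wait, expected provider idle time, and expected provider
overtime, the expectation taken over independent Bernoulli show/no-show
outcomes.  For up to ``EXACT_CUTOFF`` patients the expectation is
computed exactly by enumerating all 2^n show vectors; larger instances
fall back to seeded Monte-Carlo sampling.

The enumeration is vectorized: the clinic-day recursion runs once over a
(scenarios x patients) boolean show matrix, so repeated evaluation of
candidate assignments for a fixed probability vector (the inner loop of
the optimizer) reuses the scenario weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np

from .core import Assignment, SlotGrid
from .errors import ConfigurationError, RosterMismatchError, SizeLimitError

#: Largest patient count for which exact 2^n enumeration is attempted.
EXACT_CUTOFF = 20

_SHOW_MATRIX_CACHE: dict[int, np.ndarray] = {}


def _all_show_vectors(n: int) -> np.ndarray:
    """Boolean (2^n, n) matrix of every show vector on n patients."""
    if n not in _SHOW_MATRIX_CACHE:
        masks = np.arange(1 << n, dtype=np.uint32)
        bits = (masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1
        _SHOW_MATRIX_CACHE[n] = bits.astype(bool)
    return _SHOW_MATRIX_CACHE[n]


@dataclass(frozen=True)
class CostWeights:
    """Nonnegative weights on (total wait, idle, overtime); not all zero."""

    w_wait: float = 1.0
    w_idle: float = 1.0
    w_overtime: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_wait", "w_idle", "w_overtime"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.w_wait == self.w_idle == self.w_overtime == 0:
            raise ConfigurationError("at least one cost weight must be positive")


@dataclass(frozen=True)
class ExpectedOutcome:
    """Expected per-patient waits plus expected idle and overtime (minutes).

    ``mode`` is ``"exact"`` or ``"mc"``; Monte-Carlo outcomes record the
    sample count, seed, and standard errors of the three aggregates.
    """

    expected_wait: dict[str, float]
    expected_idle: float
    expected_overtime: float
    mode: str
    n_samples: int | None = None
    seed: int | None = None
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def total_expected_wait(self) -> float:
        return float(sum(self.expected_wait.values()))


class DayEvaluator:
    """Evaluate assignments against a fixed show-probability vector.

    Construct once per (roster, probabilities) pair via :meth:`exact` or
    :meth:`monte_carlo`, then call :meth:`outcome` for each candidate
    assignment.  Scenario weights and the show matrix are shared across
    calls, which is what makes local search over assignments affordable.
    """

    def __init__(
        self,
        grid: SlotGrid,
        show_probs: Mapping[str, float],
        shows: np.ndarray,
        weights: np.ndarray,
        mode: str,
        n_samples: int | None = None,
        seed: int | None = None,
    ) -> None:
        self.grid = grid
        self.pids = tuple(show_probs)
        self.index = {pid: i for i, pid in enumerate(self.pids)}
        self.probs = dict(show_probs)
        self._shows = shows
        self._w = weights
        self._n_shown = shows.sum(axis=1)
        self.mode = mode
        self.n_samples = n_samples
        self.seed = seed

    @classmethod
    def exact(
        cls,
        grid: SlotGrid,
        show_probs: Mapping[str, float],
        cutoff: int = EXACT_CUTOFF,
    ) -> "DayEvaluator":
        n = len(show_probs)
        if n > cutoff:
            raise SizeLimitError(
                f"{n} patients exceeds the exact-enumeration cutoff {cutoff}; "
                "use Monte-Carlo evaluation (expected_outcome_mc)"
            )
        p = np.asarray([show_probs[pid] for pid in show_probs], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ConfigurationError("show probabilities must lie in [0, 1]")
        shows = _all_show_vectors(n)
        w = np.prod(np.where(shows, p, 1.0 - p), axis=1)
        return cls(grid, show_probs, shows, w, mode="exact")

    @classmethod
    def monte_carlo(
        cls,
        grid: SlotGrid,
        show_probs: Mapping[str, float],
        n_samples: int = 10_000,
        seed: int = 0,
    ) -> "DayEvaluator":
        if n_samples < 1:
            raise ConfigurationError("n_samples must be at least 1")
        p = np.asarray([show_probs[pid] for pid in show_probs], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ConfigurationError("show probabilities must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        shows = rng.random((n_samples, len(p))) < p
        w = np.full(n_samples, 1.0 / n_samples)
        return cls(grid, show_probs, shows, w, mode="mc", n_samples=n_samples, seed=seed)

    def _check(self, assignment: Assignment) -> None:
        assignment.validate(self.grid)
        assigned = set(assignment.patient_ids())
        if assigned != set(self.pids):
            raise RosterMismatchError(
                "assignment does not cover the evaluator's patients; "
                f"extra={sorted(assigned - set(self.pids))} "
                f"missing={sorted(set(self.pids) - assigned)}"
            )

    def outcome(self, assignment: Assignment) -> ExpectedOutcome:
        self._check(assignment)
        grid = self.grid
        dur = grid.slot_duration
        free = np.zeros(self._shows.shape[0])
        exp_wait: dict[str, float] = {}
        total_wait = np.zeros_like(free)
        for pid, slot_index in assignment.service_order():
            s = self._shows[:, self.index[pid]]
            slot_start = grid.slot_start(slot_index)
            start = np.maximum(slot_start, free)
            wait = np.where(s, start - slot_start, 0.0)
            exp_wait[pid] = float(self._w @ wait)
            total_wait += wait
            free = np.where(s, start + dur, free)
        L = grid.session_length
        idle = np.maximum(L, free) - dur * self._n_shown
        overtime = np.maximum(0.0, free - L)
        stderr: dict[str, float] = {}
        if self.mode == "mc" and self.n_samples and self.n_samples > 1:
            m = self.n_samples
            stderr = {
                "total_wait": float(np.std(total_wait, ddof=1) / math.sqrt(m)),
                "idle": float(np.std(idle, ddof=1) / math.sqrt(m)),
                "overtime": float(np.std(overtime, ddof=1) / math.sqrt(m)),
            }
        return ExpectedOutcome(
            expected_wait=exp_wait,
            expected_idle=float(self._w @ idle),
            expected_overtime=float(self._w @ overtime),
            mode=self.mode,
            n_samples=self.n_samples,
            seed=self.seed,
            stderr=stderr,
        )

    def wait_exceedance(
        self, assignment: Assignment, threshold: float
    ) -> dict[str, float]:
        """Per patient, the joint probability P(shows and waits > threshold)."""
        self._check(assignment)
        grid = self.grid
        dur = grid.slot_duration
        free = np.zeros(self._shows.shape[0])
        out: dict[str, float] = {}
        for pid, slot_index in assignment.service_order():
            s = self._shows[:, self.index[pid]]
            slot_start = grid.slot_start(slot_index)
            start = np.maximum(slot_start, free)
            wait = start - slot_start
            out[pid] = float(self._w @ (s & (wait > threshold)))
            free = np.where(s, start + dur, free)
        return out


class BacklogEvaluator:
    """Exact expected outcomes via a backlog Markov chain, any roster size.

    With deterministic service equal to the slot length, the provider's
    state at the start of slot k reduces to the backlog b_k: how many
    full service durations the provider is behind schedule
    (b_k = (max(free time, slot start) - slot start) / duration, an
    integer).  Given independent shows, b evolves as
    b_{k+1} = max(0, b_k + m_k - 1) where m_k is the number of shown
    patients in slot k, and

    * the priority-r patient of slot k, when shown, waits
      (b_k + number shown ahead of it in the slot) durations, so its
      expected wait is p_r * dur * (E[b_k] + sum of earlier p's);
    * overtime = dur * final backlog;
    * idle = session length + overtime - dur * (number shown).

    Propagating the exact distribution of b_k slot by slot therefore
    reproduces the full 2^n enumeration at a cost linear in the number
    of slots — this is the evaluation backend the optimizer iterates on.
    """

    def __init__(self, grid: SlotGrid, show_probs: Mapping[str, float]) -> None:
        self.grid = grid
        self.probs = {pid: float(p) for pid, p in show_probs.items()}
        for pid, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"show probability for {pid!r} outside [0, 1]"
                )

    def _check(self, assignment: Assignment) -> None:
        assignment.validate(self.grid)
        assigned = set(assignment.patient_ids())
        if assigned != set(self.probs):
            raise RosterMismatchError(
                "assignment does not cover the evaluator's patients; "
                f"extra={sorted(assigned - set(self.probs))} "
                f"missing={sorted(set(self.probs) - assigned)}"
            )

    def outcome(self, assignment: Assignment) -> ExpectedOutcome:
        self._check(assignment)
        dur = self.grid.slot_duration
        dist = [1.0]  # P(backlog = b), starting at b = 0
        exp_wait: dict[str, float] = {}
        for slot in assignment.slots:
            e_b = sum(b * pb for b, pb in enumerate(dist))
            ahead = 0.0
            pm = [1.0]  # distribution of the slot's shown count
            for r, pid in enumerate(slot):
                p = self.probs[pid]
                exp_wait[pid] = p * dur * (e_b + ahead)
                ahead += p
                pm = [
                    (pm[m] if m < len(pm) else 0.0) * (1 - p)
                    + (pm[m - 1] * p if m > 0 else 0.0)
                    for m in range(len(pm) + 1)
                ]
            ndist = [0.0] * (len(dist) + len(slot))
            for b, pb in enumerate(dist):
                if pb == 0.0:
                    continue
                for m, pmc in enumerate(pm):
                    ndist[max(0, b + m - 1)] += pb * pmc
            while len(ndist) > 1 and ndist[-1] == 0.0:
                ndist.pop()
            dist = ndist
        e_overtime = dur * sum(b * pb for b, pb in enumerate(dist))
        e_shown = sum(self.probs.values())
        e_idle = self.grid.session_length + e_overtime - dur * e_shown
        return ExpectedOutcome(
            expected_wait=exp_wait,
            expected_idle=e_idle,
            expected_overtime=e_overtime,
            mode="exact",
        )


def expected_outcome_exact(
    assignment: Assignment,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    cutoff: int = EXACT_CUTOFF,
) -> ExpectedOutcome:
    """Exact expectation of the clinic-day recursion over all 2^n show
    vectors, each weighted by prod p^s (1-p)^(1-s)."""
    return DayEvaluator.exact(grid, show_probs, cutoff=cutoff).outcome(assignment)


def expected_outcome_mc(
    assignment: Assignment,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    n_samples: int = 10_000,
    seed: int = 0,
) -> ExpectedOutcome:
    """Seeded Monte-Carlo estimate of the expected outcome."""
    ev = DayEvaluator.monte_carlo(grid, show_probs, n_samples=n_samples, seed=seed)
    return ev.outcome(assignment)


def schedule_cost(outcome: ExpectedOutcome, weights: CostWeights) -> float:
    """w_wait * sum of expected waits + w_idle * E[idle] + w_overtime * E[overtime].

    Lower cost means higher schedule quality; the package reports quality
    only as the negation of this cost.
    """
    return (
        weights.w_wait * outcome.total_expected_wait
        + weights.w_idle * outcome.expected_idle
        + weights.w_overtime * outcome.expected_overtime
    )
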