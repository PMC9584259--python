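"""Fairness and efficiency metrics for evaluated schedules.

Three quantities: the signed percent disparity between the two groups'
mean expected waits, the statistical-parity gap (difference between the
groups' probabilities of waiting longer than a threshold, conditional on
showing up), and the optimality gap of a method's schedule cost against
a reference cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping

from .core import Assignment, Roster, SlotGrid
from .errors import MetricUndefinedError
from .evaluate import EXACT_CUTOFF, DayEvaluator, ExpectedOutcome

#: Admissible denominators for the percent wait disparity.
DISPARITY_DENOMINATORS = ("mean_of_means", "reference_mean", "overall_mean")


@dataclass(frozen=True)
class FairnessReport:
    """Bundle of fairness metrics for one evaluated assignment."""

    group_mean_wait: dict[str, float]
    disparity_percent: float
    parity_gap: float | None
    parity_threshold: float | None
    optimality_gap_percent: float | None


def group_mean_waits(
    expected_wait: Mapping[str, float],
    roster: Roster,
    show_probs: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Mean expected wait per group label.

    With ``show_probs`` the mean is conditional on attendance —
    sum of E[wait] over the group divided by the group's expected number
    of shows — which is the quantity a clinic's wait-time report
    measures (no-shows never wait, so an unconditional mean would scale
    every patient's wait by their own show probability).  Without
    ``show_probs`` it is the plain per-patient mean.
    """
    sums: dict[str, list[float]] = {}
    probs: dict[str, list[float]] = {}
    for p in roster:
        if p.patient_id in expected_wait:
            sums.setdefault(p.group, []).append(expected_wait[p.patient_id])
            if show_probs is not None:
                probs.setdefault(p.group, []).append(show_probs[p.patient_id])
    if show_probs is None:
        return {g: sum(v) / len(v) for g, v in sums.items()}
    return {
        g: (sum(v) / sum(probs[g]) if sum(probs[g]) > 0 else 0.0)
        for g, v in sums.items()
    }


def group_wait_show_sums(
    expected_wait: Mapping[str, float],
    roster: Roster,
    show_probs: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    """Per group: (sum of expected waits, expected number of shows).

    These are the pooling primitives for multi-day disparity: summing
    them over days and dividing gives the attendance-conditional group
    mean wait of the pooled population, free of the small-sample ratio
    noise a per-day percent disparity carries.
    """
    out: dict[str, tuple[float, float]] = {}
    for p in roster:
        if p.patient_id in expected_wait:
            w, q = out.get(p.group, (0.0, 0.0))
            out[p.group] = (
                w + expected_wait[p.patient_id],
                q + show_probs[p.patient_id],
            )
    return out


def disparity_from_sums(
    wait_sum_prot: float,
    show_sum_prot: float,
    wait_sum_other: float,
    show_sum_other: float,
) -> float:
    """Percent disparity from pooled group sums (mean-of-means
    denominator); 0 by convention when both group means are zero."""
    prot = wait_sum_prot / show_sum_prot if show_sum_prot > 0 else 0.0
    other = wait_sum_other / show_sum_other if show_sum_other > 0 else 0.0
    if prot == other == 0.0:
        return 0.0
    return 100.0 * (prot - other) / ((prot + other) / 2.0)


def _two_group_means(
    expected_wait: Mapping[str, float],
    roster: Roster,
    protected_group: str,
    show_probs: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    means = group_mean_waits(expected_wait, roster, show_probs)
    if protected_group not in means:
        raise MetricUndefinedError(
            f"protected group {protected_group!r} is empty on this roster"
        )
    others = [m for g, m in means.items() if g != protected_group]
    if not others:
        raise MetricUndefinedError("the non-protected group is empty on this roster")
    other = sum(others) / len(others)
    return means[protected_group], other


def wait_disparity(
    expected_wait: Mapping[str, float] | ExpectedOutcome,
    roster: Roster,
    protected_group: str,
    show_probs: Mapping[str, float] | None = None,
    denominator: str = "mean_of_means",
) -> float:
    """Signed percent difference between the protected group's mean
    expected wait and the other group's.

    Positive values mean the protected group waits longer.  Passing
    ``show_probs`` makes the group means conditional on attendance (see
    :func:`group_mean_waits`); pipelines should do so, otherwise a
    group's lower attendance rate masquerades as a shorter wait.  The
    default denominator is the average of the two group means (symmetric
    and stable when one mean is near zero); ``reference_mean`` divides
    by the non-protected group's mean and ``overall_mean`` by the roster
    mean.  When both group means are zero the disparity is 0 by
    convention.
    """
    if isinstance(expected_wait, ExpectedOutcome):
        expected_wait = expected_wait.expected_wait
    if denominator not in DISPARITY_DENOMINATORS:
        raise MetricUndefinedError(
            f"unknown denominator {denominator!r}; choose from {DISPARITY_DENOMINATORS}"
        )
    prot, other = _two_group_means(expected_wait, roster, protected_group, show_probs)
    if prot == other == 0.0:
        return 0.0
    if denominator == "mean_of_means":
        denom = (prot + other) / 2.0
    elif denominator == "reference_mean":
        denom = other
    else:
        waits = list(expected_wait.values())
        denom = sum(waits) / len(waits)
    if denom <= 0:
        raise MetricUndefinedError(
            f"disparity denominator {denominator!r} is nonpositive"
        )
    return 100.0 * (prot - other) / denom


def statistical_parity_gap(
    assignment: Assignment,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    roster: Roster,
    protected_group: str,
    wait_threshold: float = 0.0,
    mc_samples: int = 20_000,
    mc_seed: int = 0,
) -> float:
    """P(wait > threshold | protected group, shown) minus the same
    probability for the other group, over the show-vector distribution.

    Exact for rosters within the enumeration cutoff, Monte-Carlo beyond
    it.  Positive values mean shown protected-group patients are more
    likely to experience a long wait.
    """
    if len(show_probs) <= EXACT_CUTOFF:
        ev = DayEvaluator.exact(grid, show_probs)
    else:
        ev = DayEvaluator.monte_carlo(grid, show_probs, n_samples=mc_samples, seed=mc_seed)
    joint = ev.wait_exceedance(assignment, wait_threshold)
    groups = roster.groups()
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for pid, pr in joint.items():
        g = groups[pid]
        key = "prot" if g == protected_group else "other"
        num[key] = num.get(key, 0.0) + pr
        den[key] = den.get(key, 0.0) + show_probs[pid]
    if "prot" not in num:
        raise MetricUndefinedError(
            f"protected group {protected_group!r} is empty on this roster"
        )
    if "other" not in num:
        raise MetricUndefinedError("the non-protected group is empty on this roster")
    p_prot = num["prot"] / den["prot"] if den["prot"] > 0 else 0.0
    p_other = num["other"] / den["other"] if den["other"] > 0 else 0.0
    return p_prot - p_other


def optimality_gap(cost_method: float, cost_reference: float) -> float:
    """Percent excess of a method's schedule cost over the reference:
    100 * (cost_method - cost_reference) / cost_reference."""
    if not cost_reference > 0 or math.isnan(cost_reference):
        raise MetricUndefinedError(
            f"optimality gap needs a positive reference cost, got {cost_reference}"
        )
    return 100.0 * (cost_method - cost_reference) / cost_reference


def fairness_report(
    outcome: ExpectedOutcome,
    assignment: Assignment,
    grid: SlotGrid,
    show_probs: Mapping[str, float],
    roster: Roster,
    protected_group: str,
    wait_threshold: float = 0.0,
    cost_method: float | None = None,
    cost_reference: float | None = None,
) -> FairnessReport:
    """Compute the full metric bundle for one evaluated assignment."""
    gap = None
    if cost_method is not None and cost_reference is not None:
        gap = optimality_gap(cost_method, cost_reference)
    return FairnessReport(
        group_mean_wait=group_mean_waits(outcome.expected_wait, roster, show_probs),
        disparity_percent=wait_disparity(outcome, roster, protected_group, show_probs),
        parity_gap=statistical_parity_gap(
            assignment, grid, show_probs, roster, protected_group, wait_threshold
        ),
        parity_threshold=wait_threshold,
        optimality_gap_percent=gap,
    )
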