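"""Objective variants, quota constraints, and the two optimizers."""

import itertools

import numpy as np
import pytest

from fairbook import (
    Assignment,
    CostWeights,
    ObjectiveSpec,
    ObjectiveVariant,
    QuotaConstraint,
    SlotGrid,
    check_quota,
    objective_value,
    optimize_heuristic,
    optimize_oracle,
)
from fairbook.errors import ConfigurationError, InfeasibleError, SizeLimitError
from fairbook.optimize import risk_tercile_ids

from conftest import make_roster, random_instance


def brute_force_best(roster, grid, probs, spec):
    """Independent exhaustive minimizer used to re-check the oracle."""
    pids = roster.ids
    best_val = np.inf
    for combo in itertools.product(range(1, grid.n_slots + 1), repeat=len(pids)):
        buckets = [[] for _ in range(grid.n_slots)]
        for pid, s in zip(pids, combo):
            buckets[s - 1].append(pid)
        if any(len(b) > grid.capacity for b in buckets):
            continue
        a = Assignment(tuple(tuple(b) for b in buckets))
        if spec.constraints and not all(
            check_quota(a, grid, roster, c, probs).satisfied for c in spec.constraints
        ):
            continue
        best_val = min(best_val, objective_value(a, grid, probs, roster, spec))
    return best_val


class TestObjectiveValue:
    @pytest.fixture
    def one_long_wait(self):
        """Five certain-show patients; only the second-served patient of
        the final (double-booked) slot waits, exactly 30 minutes."""
        grid = SlotGrid(n_slots=5, slot_duration=30, capacity=2)
        a = Assignment((("p1",), ("p2",), ("p3",), (), ("p4", "p5")))
        probs = dict.fromkeys(("p1", "p2", "p3", "p4", "p5"), 1.0)
        roster = make_roster(probs, {"p1": "B", "p2": "B", "p3": "nonB",
                                     "p4": "nonB", "p5": "nonB"})
        return grid, a, probs, roster

    def test_traditional_vs_race_unaware_scaling(self, one_long_wait):
        grid, a, probs, roster = one_long_wait
        weights = CostWeights(1.0, 0.0, 0.0)
        trad = objective_value(
            a, grid, probs, roster, ObjectiveSpec(ObjectiveVariant.TRADITIONAL, weights)
        )
        unaware = objective_value(
            a, grid, probs, roster, ObjectiveSpec(ObjectiveVariant.RACE_UNAWARE, weights)
        )
        assert trad == pytest.approx(30.0)
        assert unaware == pytest.approx(150.0)  # n=5 times the worst wait

    def test_race_aware_equals_traditional_when_groups_equal(self):
        """With equal group mean waits the spread penalty vanishes: two
        isolated double-booked slots, each pairing one patient of each
        group, give both groups a mean wait of 15 minutes."""
        grid = SlotGrid(n_slots=4, slot_duration=30, capacity=2)
        a = Assignment((("b1", "a1"), (), (), ("a2", "b2")))
        probs = dict.fromkeys(("a1", "a2", "b1", "b2"), 1.0)
        roster = make_roster(probs, {"a1": "nonB", "a2": "nonB", "b1": "B", "b2": "B"})
        weights = CostWeights(1.0, 0.0, 0.0)
        trad = objective_value(
            a, grid, probs, roster, ObjectiveSpec(ObjectiveVariant.TRADITIONAL, weights)
        )
        aware = objective_value(
            a, grid, probs, roster, ObjectiveSpec(ObjectiveVariant.RACE_AWARE, weights)
        )
        assert aware == pytest.approx(trad)

    def test_single_group_race_aware_reduces_to_traditional(self, one_long_wait):
        grid, a, probs, _ = one_long_wait
        roster = make_roster(probs)  # everyone nonB
        weights = CostWeights(1.0, 0.0, 0.0)
        aware = objective_value(
            a, grid, probs, roster, ObjectiveSpec(ObjectiveVariant.RACE_AWARE, weights)
        )
        assert aware == pytest.approx(30.0)

    def test_race_aware_requires_roster(self, one_long_wait):
        grid, a, probs, _ = one_long_wait
        with pytest.raises(ConfigurationError):
            objective_value(
                a, grid, probs, None, ObjectiveSpec(ObjectiveVariant.RACE_AWARE)
            )


class TestOracle:
    def test_lowest_probability_patient_overbooked(self):
        """Efficiency puts the least reliable patient into the shared slot."""
        probs = {"p1": 0.9, "p2": 0.9, "p3": 0.3}
        roster = make_roster(probs)
        grid = SlotGrid(n_slots=2, slot_duration=30, capacity=2)
        best = optimize_oracle(roster, grid, probs, ObjectiveSpec())
        shared = next(slot for slot in best.slots if len(slot) == 2)
        assert "p3" in shared

    def test_perfect_schedule_when_it_exists(self):
        probs = {f"p{i}": 1.0 for i in range(3)}
        roster = make_roster(probs)
        grid = SlotGrid(n_slots=3, slot_duration=30)
        best = optimize_oracle(roster, grid, probs, ObjectiveSpec())
        assert all(len(slot) == 1 for slot in best.slots)
        assert objective_value(best, grid, probs, roster, ObjectiveSpec()) == pytest.approx(0.0)

    @pytest.mark.parametrize("variant", list(ObjectiveVariant))
    def test_oracle_attains_brute_force_minimum(self, variant):
        rng = np.random.default_rng(17)
        probs = {f"x{i}": float(rng.uniform(0.2, 0.95)) for i in range(5)}
        roster = make_roster(
            probs, {f"x{i}": ("B" if i < 2 else "nonB") for i in range(5)}
        )
        grid = SlotGrid(n_slots=3, slot_duration=30, capacity=2)
        spec = ObjectiveSpec(variant)
        best = optimize_oracle(roster, grid, probs, spec)
        assert objective_value(best, grid, probs, roster, spec) == pytest.approx(
            brute_force_best(roster, grid, probs, spec)
        )

    def test_size_limit(self):
        probs = {f"x{i}": 0.5 for i in range(9)}
        roster = make_roster(probs)
        grid = SlotGrid(n_slots=5, slot_duration=30, capacity=2)
        with pytest.raises(SizeLimitError):
            optimize_oracle(roster, grid, probs, ObjectiveSpec())


class TestHeuristic:
    def test_matches_oracle_on_small_instances(self):
        rng = np.random.default_rng(23)
        for trial in range(8):
            roster, grid, probs = random_instance(rng)
            for variant in ObjectiveVariant:
                spec = ObjectiveSpec(variant)
                v_oracle = objective_value(
                    optimize_oracle(roster, grid, probs, spec), grid, probs, roster, spec
                )
                v_heur = objective_value(
                    optimize_heuristic(roster, grid, probs, spec, seed=trial),
                    grid, probs, roster, spec,
                )
                assert v_heur == pytest.approx(v_oracle, abs=1e-6)

    def test_zero_iterations_returns_greedy(self):
        probs = {"p1": 0.9, "p2": 0.8, "p3": 0.3}
        roster = make_roster(probs)
        grid = SlotGrid(n_slots=2, slot_duration=30, capacity=2)
        greedy = optimize_heuristic(roster, grid, probs, ObjectiveSpec(), max_iters=0)
        # highest-probability patients take the leading slots; the
        # leftover lowest-probability patient overbooks the first slot
        assert greedy.slots == (("p1", "p3"), ("p2",))

    def test_seed_determinism(self):
        rng = np.random.default_rng(31)
        roster, grid, probs = random_instance(rng, n_max=6, m_max=4)
        spec = ObjectiveSpec(ObjectiveVariant.RACE_UNAWARE)
        a = optimize_heuristic(roster, grid, probs, spec, seed=99)
        b = optimize_heuristic(roster, grid, probs, spec, seed=99)
        assert a == b

    def test_improvement_over_greedy(self):
        rng = np.random.default_rng(37)
        for trial in range(5):
            roster, grid, probs = random_instance(rng, n_max=6, m_max=4)
            spec = ObjectiveSpec()
            greedy = optimize_heuristic(roster, grid, probs, spec, max_iters=0)
            final = optimize_heuristic(roster, grid, probs, spec, seed=trial)
            assert objective_value(final, grid, probs, roster, spec) <= (
                objective_value(greedy, grid, probs, roster, spec) + 1e-9
            )

    @pytest.mark.parametrize(
        "variant", [ObjectiveVariant.TRADITIONAL, ObjectiveVariant.RACE_UNAWARE]
    )
    def test_group_blindness(self, variant):
        """Group-blind variants return identical schedules after group
        labels are permuted (features and probabilities fixed)."""
        rng = np.random.default_rng(43)
        probs = {f"x{i}": float(rng.uniform(0.3, 0.95)) for i in range(6)}
        grid = SlotGrid(n_slots=4, slot_duration=30, capacity=2)
        spec = ObjectiveSpec(variant)
        r1 = make_roster(probs, {f"x{i}": ("B" if i % 2 else "nonB") for i in range(6)})
        r2 = make_roster(probs, {f"x{i}": ("nonB" if i % 2 else "B") for i in range(6)})
        assert optimize_heuristic(r1, grid, probs, spec, seed=7) == optimize_heuristic(
            r2, grid, probs, spec, seed=7
        )


class TestQuotas:
    def test_proportional_allocation_satisfies_default_quotas(self):
        """All slots desirable, held 30/70 by the two groups: minima of
        20% and 60% are met."""
        probs = {f"x{i}": 0.9 for i in range(10)}
        groups = {f"x{i}": ("B" if i < 3 else "nonB") for i in range(10)}
        roster = make_roster(probs, groups)
        grid = SlotGrid(n_slots=10, slot_duration=30, capacity=2)
        a = Assignment(tuple((f"x{i}",) for i in range(10)))
        quota = QuotaConstraint.group_quota({"B": 0.2, "nonB": 0.6})
        res = check_quota(a, grid, roster, quota, probs)
        assert res.satisfied
        assert res.attained == pytest.approx({"B": 0.3, "nonB": 0.7})

    def test_zero_minimum_always_satisfied(self, demo_grid, demo_assignment, demo_roster):
        quota = QuotaConstraint.group_quota({"B": 0.0, "nonB": 0.0})
        res = check_quota(
            demo_assignment, demo_grid, demo_roster, quota, demo_roster.show_probs()
        )
        assert res.satisfied

    def test_worked_example_group_quota_unsatisfied(
        self, demo_grid, demo_assignment, demo_roster
    ):
        """Both desirable slots (1 and 4) are held by non-minority
        patients, so a 50% minority quota fails with attained 0."""
        quota = QuotaConstraint.group_quota({"B": 0.5})
        res = check_quota(
            demo_assignment, demo_grid, demo_roster, quota, demo_roster.show_probs()
        )
        assert not res.satisfied
        assert res.attained["B"] == 0.0
        assert res.n_desirable == 2

    def test_no_desirable_slot_is_unsatisfied_with_nan(self):
        probs = {f"x{i}": 0.5 for i in range(4)}
        roster = make_roster(probs, {f"x{i}": "B" for i in range(4)})
        grid = SlotGrid(n_slots=2, slot_duration=30, capacity=2)
        a = Assignment((("x0", "x1"), ("x2", "x3")))
        res = check_quota(a, grid, roster, QuotaConstraint.group_quota({"B": 0.1}), probs)
        assert not res.satisfied
        assert np.isnan(res.attained["B"])

    def test_risk_tercile_boundary(self):
        probs = {"a": 0.2, "b": 0.2, "c": 0.8, "d": 0.9}
        # ceil(4/3) = 2 highest-risk patients; tie at 0.2 broken by id
        assert risk_tercile_ids(probs) == {"a", "b"}

    def test_risk_quota_counts_top_tercile(self, demo_grid, demo_assignment, demo_roster):
        probs = demo_roster.show_probs()
        # top risk tercile of {0.9,0.9,0.45,0.4,0.35} is {e, d}; both sit
        # in undesirable slots, so a 50% desirable-slot reservation fails
        quota = QuotaConstraint.risk_quota(0.5)
        res = check_quota(demo_assignment, demo_grid, demo_roster, quota, probs)
        assert not res.satisfied
        assert res.attained["top_risk_tercile"] == 0.0

    def test_optimizers_respect_quotas(self):
        rng = np.random.default_rng(53)
        quota = QuotaConstraint.risk_quota(0.25)
        for trial in range(5):
            roster, grid, probs = random_instance(rng, n_max=5, m_max=4)
            if grid.n_slots < 3 or len(roster) <= grid.n_slots:
                continue
            spec = ObjectiveSpec(constraints=(quota,))
            try:
                best = optimize_oracle(roster, grid, probs, spec)
            except InfeasibleError:
                continue
            assert check_quota(best, grid, roster, quota, probs).satisfied
            heur = optimize_heuristic(roster, grid, probs, spec, seed=trial)
            assert check_quota(heur, grid, roster, quota, probs).satisfied

    def test_infeasible_quota_raises(self):
        probs = {"x0": 0.9, "x1": 0.8, "x2": 0.3}
        roster = make_roster(probs, {"x0": "B", "x1": "nonB", "x2": "nonB"})
        grid = SlotGrid(n_slots=2, slot_duration=30, capacity=2)
        # both groups cannot each hold 100% of the desirable slots
        spec = ObjectiveSpec(
            constraints=(QuotaConstraint.group_quota({"B": 1.0, "nonB": 1.0}),)
        )
        with pytest.raises(InfeasibleError, match="GROUP_QUOTA"):
            optimize_oracle(roster, grid, probs, spec)
        with pytest.raises(InfeasibleError):
            optimize_heuristic(roster, grid, probs, spec, seed=0)

    def test_quota_validation(self):
        with pytest.raises(ConfigurationError):
            QuotaConstraint.group_quota({"B": 1.5})
        with pytest.raises(ConfigurationError):
            QuotaConstraint.risk_quota(-0.1)
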