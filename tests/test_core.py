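"""Clinic-day recursion, slot desirability, and the domain invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairbook import (
    Assignment,
    Desirability,
    PatientRecord,
    Roster,
    SlotGrid,
    classify_slots,
    patient_slot_labels,
    simulate_day,
)
from fairbook.errors import InvalidAssignmentError, RosterMismatchError
from fairbook.io import read_assignment, read_roster, write_assignment, write_roster

from conftest import random_assignment


class TestSimulateDay:
    def test_all_show_worked_example(self, demo_grid, demo_assignment):
        """With everyone showing, the second double-booked patient and the
        following slot's patient each wait a full slot, and the delay
        ripples to the last slot."""
        out = simulate_day(demo_assignment, demo_grid, dict.fromkeys("abcde", 1))
        assert out.waits == {"a": 0, "d": 0, "e": 30, "c": 30, "b": 30}
        assert out.overtime == 30  # 5 x 30 min of service in a 120-min session
        assert out.idle == 0
        assert out.last_completion == 150

    def test_partial_show_day(self, demo_grid, demo_assignment):
        """Only a, d, e show: e still waits behind d, the session ends
        half an hour early, no overtime."""
        shows = {"a": 1, "d": 1, "e": 1, "c": 0, "b": 0}
        out = simulate_day(demo_assignment, demo_grid, shows)
        assert out.waits == {"a": 0, "d": 0, "e": 30, "c": 0, "b": 0}
        assert out.last_completion == 90
        assert out.idle == 30
        assert out.overtime == 0

    def test_saturated_punctual_schedule(self):
        grid = SlotGrid(n_slots=3, slot_duration=30)
        a = Assignment((("p1",), ("p2",), ("p3",)))
        out = simulate_day(a, grid, {"p1": 1, "p2": 1, "p3": 1})
        assert all(w == 0 for w in out.waits.values())
        assert out.idle == 0 and out.overtime == 0

    def test_nobody_shows(self, demo_grid, demo_assignment):
        out = simulate_day(demo_assignment, demo_grid, dict.fromkeys("abcde", 0))
        assert out.total_wait == 0
        assert out.idle == demo_grid.session_length
        assert out.overtime == 0 and out.last_completion == 0

    def test_unknown_patient_rejected(self, demo_grid, demo_assignment):
        shows = dict.fromkeys("abcdz", 1)
        with pytest.raises(RosterMismatchError):
            simulate_day(demo_assignment, demo_grid, shows)

    def test_capacity_violation_rejected(self):
        grid = SlotGrid(n_slots=2, slot_duration=30, capacity=2)
        overfull = Assignment((("p1", "p2", "p3"), ()))
        with pytest.raises(InvalidAssignmentError):
            simulate_day(overfull, grid, {"p1": 1, "p2": 1, "p3": 1})


class TestClassifySlots:
    def test_worked_example_labels(self, demo_grid, demo_assignment):
        labels = classify_slots(demo_assignment, demo_grid)
        assert [l.value for l in labels] == [
            "DESIRABLE", "UNDESIRABLE", "UNDESIRABLE", "DESIRABLE",
        ]
        per_patient = patient_slot_labels(demo_assignment, demo_grid)
        assert per_patient["a"] is Desirability.DESIRABLE
        assert per_patient["e"] is Desirability.UNDESIRABLE
        assert per_patient["c"] is Desirability.UNDESIRABLE

    def test_no_overbooking_all_desirable(self):
        grid = SlotGrid(n_slots=3, slot_duration=30)
        a = Assignment((("p1",), ("p2",), ()))
        assert set(classify_slots(a, grid)) == {Desirability.DESIRABLE}

    def test_adjacent_overbooked_slots_shadow(self):
        grid = SlotGrid(n_slots=4, slot_duration=30, capacity=2)
        a = Assignment((("p1", "p2"), ("p3", "p4"), ("p5",), ("p6",)))
        labels = [l.value for l in classify_slots(a, grid)]
        assert labels == ["UNDESIRABLE", "UNDESIRABLE", "UNDESIRABLE", "DESIRABLE"]


@st.composite
def day_instances(draw):
    m = draw(st.integers(min_value=1, max_value=5))
    n = draw(st.integers(min_value=1, max_value=min(2 * m, 8)))
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    rng = np.random.default_rng(seed)
    pids = [f"x{i}" for i in range(n)]
    grid = SlotGrid(n_slots=m, slot_duration=30, capacity=2)
    assignment = random_assignment(rng, pids, grid)
    shows = {pid: int(rng.integers(2)) for pid in pids}
    return grid, assignment, shows


@settings(max_examples=120, derandomize=True)
@given(day_instances())
def test_conservation_identity(instance):
    """Provider time budget: span of the worked day equals service time
    plus idle, exactly, on any instance."""
    grid, assignment, shows = instance
    out = simulate_day(assignment, grid, shows)
    span = max(grid.session_length, out.last_completion)
    assert span == grid.slot_duration * out.n_shown + out.idle
    assert out.overtime == max(0, out.last_completion - grid.session_length)
    assert all(w >= 0 for w in out.waits.values())


@settings(max_examples=120, derandomize=True)
@given(day_instances())
def test_show_flip_monotonicity(instance):
    """Turning a no-show into a show never shortens any other shown
    patient's wait, the overtime, or the total busy time."""
    grid, assignment, shows = instance
    absent = [pid for pid, s in shows.items() if s == 0]
    if not absent:
        return
    before = simulate_day(assignment, grid, shows)
    flipped = dict(shows)
    flipped[absent[0]] = 1
    after = simulate_day(assignment, grid, flipped)
    for pid, s in shows.items():
        if s == 1:
            assert after.waits[pid] >= before.waits[pid]
    assert after.overtime >= before.overtime
    assert after.last_completion >= before.last_completion


class TestDomainTypes:
    def test_show_prob_bounds(self):
        with pytest.raises(ValueError):
            PatientRecord("p", "B", show_prob=1.5)

    def test_feature_partitions_disjoint(self):
        with pytest.raises(ValueError):
            PatientRecord("p", "B", ses={"x": 1.0}, history={"x": 2.0})

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            Roster((PatientRecord("p", "B"), PatientRecord("p", "nonB")))

    def test_grid_geometry(self):
        grid = SlotGrid(n_slots=4, slot_duration=30, session_start_minute=540)
        assert grid.session_end_minute - grid.session_start_minute == 120
        assert [grid.slot_start(i) for i in (1, 2, 3, 4)] == [0, 30, 60, 90]

    def test_assignment_covers_roster(self, demo_grid, demo_assignment, demo_roster):
        demo_assignment.validate(demo_grid, demo_roster)
        short = Assignment((("a",), ("d", "e"), ("c",), ()))
        with pytest.raises(RosterMismatchError):
            short.validate(demo_grid, demo_roster)


class TestDelimitedText:
    def test_roster_round_trip(self, tmp_path, demo_roster):
        path = tmp_path / "roster.csv"
        write_roster(demo_roster, path)
        back = read_roster(path)
        assert back.ids == demo_roster.ids
        for p, q in zip(demo_roster, back):
            assert p.group == q.group
            assert p.ses == pytest.approx(q.ses)
            assert p.show_prob == pytest.approx(q.show_prob)

    def test_assignment_round_trip(self, tmp_path, demo_assignment):
        path = tmp_path / "assignment.csv"
        write_assignment(demo_assignment, path)
        back = read_assignment(path, n_slots=4)
        assert back == demo_assignment

    def test_history_features_partition(self, tmp_path):
        roster = Roster(
            (
                PatientRecord(
                    "p1",
                    "B",
                    ses={"income_index": 0.3},
                    history={"past_show_count": 4.0, "past_visit_count": 6.0},
                ),
            )
        )
        path = tmp_path / "roster.csv"
        write_roster(roster, path)
        back = read_roster(path)
        assert set(back.by_id("p1").history) == {"past_show_count", "past_visit_count"}
        assert set(back.by_id("p1").ses) == {"income_index"}
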