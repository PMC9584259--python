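import numpy as np
import pytest

from fairbook import Assignment, PatientRecord, Roster, SlotGrid


@pytest.fixture
def demo_grid():
    """Four 30-minute slots, 9:00-11:00, double-booking allowed."""
    return SlotGrid(n_slots=4, slot_duration=30, session_start_minute=540, capacity=2)


@pytest.fixture
def demo_assignment():
    """a alone in slot 1, d+e double-booked in slot 2 (d first), c in
    slot 3, b in slot 4."""
    return Assignment((("a",), ("d", "e"), ("c",), ("b",)))


@pytest.fixture
def demo_roster():
    from fairbook.examples import demo_roster as _demo

    return _demo()


def make_roster(probs, groups=None):
    """Roster from {patient_id: show_prob}, optional {patient_id: group}."""
    groups = groups or {}
    return Roster(
        tuple(
            PatientRecord(pid, groups.get(pid, "nonB"), show_prob=p)
            for pid, p in probs.items()
        )
    )


def random_instance(rng, n_max=6, m_max=4, capacity=2, two_groups=True):
    """A random small scheduling instance (roster, grid, probs)."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        m = int(rng.integers(1, m_max + 1))
        if n <= m * capacity:
            break
    probs = {f"x{i}": float(rng.uniform(0.15, 0.99)) for i in range(n)}
    if two_groups and n >= 2:
        labels = ["B", "nonB"] + [
            ("B" if rng.random() < 0.4 else "nonB") for _ in range(n - 2)
        ]
    else:
        labels = ["nonB"] * n
    groups = {f"x{i}": labels[i] for i in range(n)}
    grid = SlotGrid(n_slots=m, slot_duration=30, capacity=capacity)
    return make_roster(probs, groups), grid, probs


def random_assignment(rng, pids, grid):
    """A random capacity-feasible assignment of pids onto grid."""
    pids = list(pids)
    rng.shuffle(pids)
    buckets = [[] for _ in range(grid.n_slots)]
    for pid in pids:
        open_slots = [i for i in range(grid.n_slots) if len(buckets[i]) < grid.capacity]
        buckets[open_slots[int(rng.integers(len(open_slots)))]].append(pid)
    return Assignment(tuple(tuple(b) for b in buckets))
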