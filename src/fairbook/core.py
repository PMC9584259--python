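"""Clinic-day primitives.

A clinic session is a grid of equally long appointment slots served by a
single provider.  Patients are booked into slots, possibly two to a slot
(overbooking), and either show up punctually at their slot start or not at
all.  The provider serves shown patients in (slot, within-slot priority)
order, each for exactly one slot duration.  This module holds the domain
types and the deterministic recursion that turns one realization of
show/no-show outcomes into per-patient waits, provider idle time, and
provider overtime.

All times are integer minutes measured from the session start, which keeps
the recursion exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from collections.abc import Iterator, Mapping

from .errors import InvalidAssignmentError, RosterMismatchError

#: Feature names conventionally placed in the history partition of a
#: patient record; every other feature column is socio-economic (SES).
HISTORY_FEATURE_NAMES = ("past_show_count", "past_visit_count")


def is_history_feature(name: str) -> bool:
    """True if a feature name belongs to the history partition by convention
    (one of :data:`HISTORY_FEATURE_NAMES` or prefixed ``hist_``)."""
    return name in HISTORY_FEATURE_NAMES or name.startswith("hist_")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: group label, partitioned features, show probability.

    ``ses`` holds socio-economic features (income index, employment,
    marital status, ...); ``history`` holds attendance-history summaries
    (past show count, past visit count).  The two partitions must not
    share names.  ``show_prob`` is the latent truth for synthetic
    patients and a model prediction inside pipelines; it may be ``None``
    when not yet known.
    """

    patient_id: str
    group: str
    ses: Mapping[str, float] = field(default_factory=dict)
    history: Mapping[str, float] = field(default_factory=dict)
    show_prob: float | None = None

    def __post_init__(self) -> None:
        overlap = set(self.ses) & set(self.history)
        if overlap:
            raise ValueError(
                f"features in both SES and history partitions: {sorted(overlap)}"
            )
        if self.show_prob is not None and not 0.0 <= self.show_prob <= 1.0:
            raise ValueError(f"show_prob must lie in [0, 1], got {self.show_prob}")

    def feature(self, name: str) -> float:
        """Look up a feature by name across both partitions."""
        if name in self.ses:
            return float(self.ses[name])
        if name in self.history:
            return float(self.history[name])
        raise KeyError(name)


@dataclass(frozen=True)
class Roster:
    """An ordered collection of patients with unique identifiers."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id in roster: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.patient_id for p in self.patients)

    def by_id(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def groups(self) -> dict[str, str]:
        """patient_id -> group label."""
        return {p.patient_id: p.group for p in self.patients}

    def group_labels(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.patients:
            seen.setdefault(p.group, None)
        return tuple(seen)

    def show_probs(self) -> dict[str, float]:
        """patient_id -> show probability; requires every record to carry one."""
        missing = [p.patient_id for p in self.patients if p.show_prob is None]
        if missing:
            raise ValueError(f"patients without show_prob: {missing}")
        return {p.patient_id: float(p.show_prob) for p in self.patients}  # type: ignore[arg-type]


@dataclass(frozen=True)
class SlotGrid:
    """A clinic session of ``n_slots`` equally long appointment slots.

    ``session_start_minute`` is minutes after midnight (540 = 9:00 am);
    the session end is derived as start + n_slots * slot_duration.
    ``capacity`` bounds how many patients may share one slot (2 =
    double-booking at most).
    """

    n_slots: int
    slot_duration: int = 30
    session_start_minute: int = 9 * 60
    capacity: int = 2

    def __post_init__(self) -> None:
        if self.n_slots < 1:
            raise ValueError("n_slots must be positive")
        if self.slot_duration < 1:
            raise ValueError("slot_duration must be positive")
        if self.capacity < 1:
            raise ValueError("capacity must be positive")

    @property
    def session_length(self) -> int:
        """Session length in minutes."""
        return self.n_slots * self.slot_duration

    @property
    def session_end_minute(self) -> int:
        return self.session_start_minute + self.session_length

    def slot_start(self, slot_index: int) -> int:
        """Start of a 1-based slot, in minutes from session start."""
        if not 1 <= slot_index <= self.n_slots:
            raise ValueError(f"slot index {slot_index} outside 1..{self.n_slots}")
        return (slot_index - 1) * self.slot_duration


@dataclass(frozen=True)
class Assignment:
    """A many-to-one booking of patients into slots.

    ``slots[i]`` is the ordered tuple of patient ids booked into slot
    ``i + 1``; tuple order is the within-slot service priority (first
    element is served first when both show).
    """

    slots: tuple[tuple[str, ...], ...]

    @classmethod
    def from_mapping(
        cls,
        slot_of: Mapping[str, int],
        n_slots: int,
        priority: Mapping[str, int] | None = None,
    ) -> "Assignment":
        """Build from patient -> 1-based slot index, with optional explicit
        within-slot priorities (lower serves first; default: mapping order)."""
        buckets: list[list[str]] = [[] for _ in range(n_slots)]
        for pid, s in slot_of.items():
            if not 1 <= s <= n_slots:
                raise InvalidAssignmentError(
                    f"patient {pid!r} assigned to slot {s}, outside 1..{n_slots}"
                )
            buckets[s - 1].append(pid)
        if priority is not None:
            for b in buckets:
                b.sort(key=lambda pid: (priority.get(pid, 0), pid))
        return cls(tuple(tuple(b) for b in buckets))

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    def patient_ids(self) -> tuple[str, ...]:
        return tuple(pid for slot in self.slots for pid in slot)

    def slot_of(self) -> dict[str, int]:
        """patient_id -> 1-based slot index."""
        return {pid: i + 1 for i, slot in enumerate(self.slots) for pid in slot}

    def service_order(self) -> tuple[tuple[str, int], ...]:
        """(patient_id, slot_index) pairs in provider service order."""
        return tuple(
            (pid, i + 1) for i, slot in enumerate(self.slots) for pid in slot
        )

    def validate(self, grid: SlotGrid, roster: Roster | None = None) -> None:
        """Raise unless the assignment is well formed for ``grid`` (and
        covers ``roster`` exactly, when given)."""
        if self.n_slots != grid.n_slots:
            raise InvalidAssignmentError(
                f"assignment has {self.n_slots} slots, grid has {grid.n_slots}"
            )
        pids = self.patient_ids()
        if len(set(pids)) != len(pids):
            raise InvalidAssignmentError("a patient appears in more than one slot")
        for i, slot in enumerate(self.slots):
            if len(slot) > grid.capacity:
                raise InvalidAssignmentError(
                    f"slot {i + 1} holds {len(slot)} patients, capacity {grid.capacity}"
                )
        if roster is not None:
            assigned, rostered = set(pids), set(roster.ids)
            if assigned - rostered:
                raise RosterMismatchError(
                    f"assignment references unknown patients: {sorted(assigned - rostered)}"
                )
            if rostered - assigned:
                raise RosterMismatchError(
                    f"rostered patients left unassigned: {sorted(rostered - assigned)}"
                )


@dataclass(frozen=True)
class DayOutcome:
    """Realized outcome of one clinic day.

    Waits are per patient (zero for no-shows); ``idle`` and ``overtime``
    are provider totals.  ``last_completion`` is the completion time of
    the last served patient in minutes from session start (0 when nobody
    shows), retained so conservation identities can be checked.
    """

    waits: dict[str, int]
    idle: int
    overtime: int
    last_completion: int
    n_shown: int

    @property
    def total_wait(self) -> int:
        return sum(self.waits.values())


class Desirability(str, enum.Enum):
    DESIRABLE = "DESIRABLE"
    UNDESIRABLE = "UNDESIRABLE"


def simulate_day(
    assignment: Assignment, grid: SlotGrid, shows: Mapping[str, int]
) -> DayOutcome:
    """Run the deterministic clinic-day recursion for one show realization.

    Shown patients are served in (slot, priority) order; each service
    starts at max(own slot start, provider free time), lasts exactly one
    slot duration, and the patient's wait is service start minus slot
    start.  No-shows consume no provider time and wait zero.
    """
    assignment.validate(grid)
    pids = set(assignment.patient_ids())
    if set(shows) != pids:
        raise RosterMismatchError(
            "show vector must cover exactly the assigned patients; "
            f"extra={sorted(set(shows) - pids)} missing={sorted(pids - set(shows))}"
        )
    waits: dict[str, int] = {}
    free = 0
    n_shown = 0
    for pid, slot_index in assignment.service_order():
        if not shows[pid]:
            waits[pid] = 0
            continue
        slot_start = grid.slot_start(slot_index)
        start = max(slot_start, free)
        waits[pid] = start - slot_start
        free = start + grid.slot_duration
        n_shown += 1
    session_len = grid.session_length
    idle = max(session_len, free) - grid.slot_duration * n_shown
    overtime = max(0, free - session_len)
    return DayOutcome(
        waits=waits,
        idle=idle,
        overtime=overtime,
        last_completion=free,
        n_shown=n_shown,
    )


def classify_slots(
    assignment: Assignment, grid: SlotGrid
) -> tuple[Desirability, ...]:
    """Label each slot DESIRABLE or UNDESIRABLE.

    A slot is undesirable iff it is overbooked (holds at least two
    patients) or immediately follows an overbooked slot; such slots carry
    longer expected waits.  A patient inherits its slot's label.
    """
    assignment.validate(grid)
    overbooked = [len(slot) >= 2 for slot in assignment.slots]
    labels = []
    for i in range(grid.n_slots):
        bad = overbooked[i] or (i > 0 and overbooked[i - 1])
        labels.append(Desirability.UNDESIRABLE if bad else Desirability.DESIRABLE)
    return tuple(labels)


def patient_slot_labels(
    assignment: Assignment, grid: SlotGrid
) -> dict[str, Desirability]:
    """patient_id -> desirability label of the slot the patient holds."""
    labels = classify_slots(assignment, grid)
    return {
        pid: labels[slot_index - 1]
        for pid, slot_index in assignment.service_order()
    }
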