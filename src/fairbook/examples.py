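"""The packaged worked example: five patients, four 30-minute slots.

A clinic session runs 9:00–11:00 with four 30-minute slots.  Patient a
holds slot 1 alone, patients d and e are double-booked into slot 2 (d
served first), patient c holds slot 3, and patient b holds slot 4.
With everyone showing up, e waits 30 minutes behind d and the delay
propagates to c (another 30-minute wait); a never waits, and b waits
only when c, d and e all show.  Slots 2 and 3 are the undesirable ones.

The same instance ships as CSV files under ``fairbook/data`` for use
from the command line.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import Assignment, PatientRecord, Roster, SlotGrid


def demo_grid() -> SlotGrid:
    return SlotGrid(n_slots=4, slot_duration=30, session_start_minute=9 * 60, capacity=2)


def demo_roster() -> Roster:
    """Two high-show-probability patients (a, b) and three low ones
    (c, d, e), with plausible feature values."""
    recs = (
        PatientRecord("a", "nonB", ses={"income_index": 1.2, "employed": 1, "married": 1}, show_prob=0.90),
        PatientRecord("b", "nonB", ses={"income_index": 0.9, "employed": 1, "married": 0}, show_prob=0.90),
        PatientRecord("c", "B", ses={"income_index": -0.6, "employed": 0, "married": 1}, show_prob=0.45),
        PatientRecord("d", "B", ses={"income_index": -0.8, "employed": 0, "married": 0}, show_prob=0.40),
        PatientRecord("e", "B", ses={"income_index": -1.1, "employed": 0, "married": 1}, show_prob=0.35),
    )
    return Roster(recs)


def demo_assignment() -> Assignment:
    return Assignment((("a",), ("d", "e"), ("c",), ("b",)))


def demo_paths() -> tuple[Path, Path]:
    """Paths of the packaged roster and assignment CSV files."""
    base = resources.files("fairbook") / "data"
    return Path(str(base / "demo_roster.csv")), Path(str(base / "demo_assignment.csv"))
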