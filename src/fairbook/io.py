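"""Delimited-text readers and writers for rosters and assignments.

Roster files are comma-separated with a header row and columns
``patient_id``, ``group``, one column per feature, and an optional
``show_prob`` column.  Feature columns are partitioned by name: columns
listed in :data:`fairbook.core.HISTORY_FEATURE_NAMES` (or prefixed
``hist_``) are history features, everything else is socio-economic.

Assignment files have columns ``patient_id``, ``slot_index`` (1-based)
and ``priority`` (lower = served first within a slot).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import Assignment, PatientRecord, Roster, is_history_feature

_ROSTER_FIXED = ("patient_id", "group", "show_prob")


def read_roster(path: str | Path) -> Roster:
    df = pd.read_csv(path, dtype={"patient_id": str, "group": str})
    for col in ("patient_id", "group"):
        if col not in df.columns:
            raise ValueError(f"roster file {path} lacks required column {col!r}")
    feature_cols = [c for c in df.columns if c not in _ROSTER_FIXED]
    has_prob = "show_prob" in df.columns
    patients = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        ses = {c: float(rec[c]) for c in feature_cols if not is_history_feature(c)}
        hist = {c: float(rec[c]) for c in feature_cols if is_history_feature(c)}
        prob = rec["show_prob"] if has_prob else None
        if prob is not None and pd.isna(prob):
            prob = None
        patients.append(
            PatientRecord(
                patient_id=str(rec["patient_id"]),
                group=str(rec["group"]),
                ses=ses,
                history=hist,
                show_prob=None if prob is None else float(prob),
            )
        )
    return Roster(tuple(patients))


def write_roster(roster: Roster, path: str | Path) -> None:
    feature_names: list[str] = []
    for p in roster:
        for name in list(p.ses) + list(p.history):
            if name not in feature_names:
                feature_names.append(name)
    rows = []
    for p in roster:
        row: dict[str, object] = {"patient_id": p.patient_id, "group": p.group}
        for name in feature_names:
            row[name] = {**p.ses, **p.history}.get(name)
        row["show_prob"] = p.show_prob
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment(path: str | Path, n_slots: int) -> Assignment:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "slot_index"):
        if col not in df.columns:
            raise ValueError(f"assignment file {path} lacks required column {col!r}")
    priority = None
    if "priority" in df.columns:
        priority = dict(zip(df["patient_id"], df["priority"].astype(int)))
    slot_of = dict(zip(df["patient_id"], df["slot_index"].astype(int)))
    return Assignment.from_mapping(slot_of, n_slots=n_slots, priority=priority)


def write_assignment(assignment: Assignment, path: str | Path) -> None:
    rows = []
    for i, slot in enumerate(assignment.slots):
        for rank, pid in enumerate(slot, start=1):
            rows.append(
                {"patient_id": pid, "slot_index": i + 1, "priority": rank}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
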