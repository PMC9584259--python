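"""YAML run-configuration parsing.

A run config is a nested key-value document with up to five sections:

.. code-block:: yaml

    population:            # synthetic population parameters
      n_patients: 2000
      fraction_group_b: 0.30
      seed: 1
    grid:
      n_slots: 10
      slot_duration: 30
      capacity: 2
    weights: {w_wait: 1.0, w_idle: 1.0, w_overtime: 1.0}
    objective:
      variant: TRADITIONAL     # TRADITIONAL | RACE_AWARE | RACE_UNAWARE
      constraints:
        - {kind: GROUP_QUOTA, minima: {B: 0.2, nonB: 0.6}}
        - {kind: RISK_QUOTA, min_fraction: 0.2}
    experiment:
      n_train: 2000
      n_patients: 12
      n_days: 200
      methods: [SOTA, NO_ML, NO_SES, RACE_AWARE, RACE_UNAWARE]
      master_seed: 1

Unknown keys raise a ``ConfigurationError`` naming the section and key.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .bench import ExperimentConfig
from .core import SlotGrid
from .errors import ConfigurationError
from .evaluate import CostWeights
from .optimize import ObjectiveSpec, ObjectiveVariant, QuotaConstraint, QuotaKind
from .synth import PopulationConfig


def _build(cls, section: str, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"config section {section!r}: unknown keys {sorted(unknown)} "
            f"(allowed: {sorted(names)})"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"config section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> dict[str, Any]:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping at top level")
    return raw


def population_from(raw: dict[str, Any]) -> PopulationConfig:
    return _build(PopulationConfig, "population", dict(raw.get("population", {})))


def grid_from(raw: dict[str, Any]) -> SlotGrid:
    return _build(SlotGrid, "grid", dict(raw.get("grid", {})))


def weights_from(raw: dict[str, Any]) -> CostWeights:
    return _build(CostWeights, "weights", dict(raw.get("weights", {})))


def objective_from(raw: dict[str, Any]) -> ObjectiveSpec:
    section = dict(raw.get("objective", {}))
    variant_name = str(section.pop("variant", "TRADITIONAL"))
    try:
        variant = ObjectiveVariant(variant_name)
    except ValueError as exc:
        raise ConfigurationError(
            f"config section 'objective': unknown variant {variant_name!r} "
            f"(choose from {[v.value for v in ObjectiveVariant]})"
        ) from exc
    constraints = []
    for i, c in enumerate(section.pop("constraints", []) or []):
        c = dict(c)
        kind_name = str(c.pop("kind", ""))
        try:
            kind = QuotaKind(kind_name)
        except ValueError as exc:
            raise ConfigurationError(
                f"config objective.constraints[{i}]: unknown kind {kind_name!r}"
            ) from exc
        if kind == QuotaKind.GROUP_QUOTA:
            constraints.append(QuotaConstraint.group_quota(c.pop("minima", {})))
        else:
            constraints.append(QuotaConstraint.risk_quota(c.pop("min_fraction", -1.0)))
        if c:
            raise ConfigurationError(
                f"config objective.constraints[{i}]: unknown keys {sorted(c)}"
            )
    if section:
        raise ConfigurationError(
            f"config section 'objective': unknown keys {sorted(section)}"
        )
    return ObjectiveSpec(
        variant=variant, weights=weights_from(raw), constraints=tuple(constraints)
    )


def experiment_from(raw: dict[str, Any]) -> ExperimentConfig:
    section = dict(raw.get("experiment", {}))
    if "methods" in section:
        section["methods"] = tuple(section["methods"])
    grid = grid_from(raw)
    section.setdefault("n_slots", grid.n_slots)
    section.setdefault("slot_duration", grid.slot_duration)
    section.setdefault("capacity", grid.capacity)
    section["population"] = population_from(raw)
    section["weights"] = weights_from(raw)
    return _build(ExperimentConfig, "experiment", section)
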