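"""End-to-end benchmark: the four-way method comparison.

Five named methods cross a show-model regime with an objective variant:

=============  ===========  =============
method         show model   objective
=============  ===========  =============
SOTA           FULL         TRADITIONAL
NO_ML          NONE         TRADITIONAL
NO_SES         NO_SES       TRADITIONAL
RACE_AWARE     FULL         RACE_AWARE
RACE_UNAWARE   FULL         RACE_UNAWARE
=============  ===========  =============

Each replicated clinic day draws a fresh roster from the synthetic
population, computes every method's predictions with models fitted once
on a large training population, optimizes the day's schedule under the
method's objective, and then evaluates the resulting assignment under
the *latent true* show probabilities — so a method's prediction quality
shows up as realized schedule cost, and its fairness as realized wait
disparity.  Optimality gaps are taken day-by-day against the SOTA
method's true schedule cost on the same day.  Everything derives from
one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Roster, SlotGrid
from .errors import ConfigurationError
from .evaluate import CostWeights, expected_outcome_exact, schedule_cost
from .metrics import disparity_from_sums, group_wait_show_sums, wait_disparity
from .models import Regime, ShowModel, fit_show_model, predict_roster
from .optimize import ObjectiveSpec, ObjectiveVariant, optimize_heuristic
from .synth import (
    GROUP_MINORITY,
    PopulationConfig,
    attach_history_features,
    generate_history,
    generate_population,
)


@dataclass(frozen=True)
class MethodSpec:
    name: str
    regime: Regime
    variant: ObjectiveVariant


METHODS: dict[str, MethodSpec] = {
    "SOTA": MethodSpec("SOTA", Regime.FULL, ObjectiveVariant.TRADITIONAL),
    "NO_ML": MethodSpec("NO_ML", Regime.NONE, ObjectiveVariant.TRADITIONAL),
    "NO_SES": MethodSpec("NO_SES", Regime.NO_SES, ObjectiveVariant.TRADITIONAL),
    "RACE_AWARE": MethodSpec("RACE_AWARE", Regime.FULL, ObjectiveVariant.RACE_AWARE),
    "RACE_UNAWARE": MethodSpec(
        "RACE_UNAWARE", Regime.FULL, ObjectiveVariant.RACE_UNAWARE
    ),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one comparison run.

    A day books ``n_patients`` into ``n_slots`` slots (default 12 into
    10, i.e. two forced double-bookings), small enough for exact
    2^n evaluation.  ``n_train`` patients are generated once to fit the
    show models.  Every random stage is derived from ``master_seed``.
    """

    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_train: int = 2000
    n_patients: int = 12
    n_slots: int = 10
    slot_duration: int = 30
    capacity: int = 2
    weights: CostWeights = field(default_factory=CostWeights)
    methods: tuple[str, ...] = tuple(METHODS)
    n_days: int = 200
    master_seed: int = 0
    protected_group: str = GROUP_MINORITY
    heuristic_starts: int = 1
    heuristic_iters: int = 60
    heuristic_kicks: int = 5

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ConfigurationError("n_days must be at least 1")
        if not self.methods:
            raise ConfigurationError("method list must be nonempty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ConfigurationError(
                f"unknown methods {unknown}; choose from {sorted(METHODS)}"
            )
        if self.n_patients > self.n_slots * self.capacity:
            raise ConfigurationError("roster does not fit the slot grid capacity")


@dataclass(frozen=True)
class ComparisonTable:
    """Aggregated comparison: one row per method with mean/SE of the
    optimality gap (% vs SOTA, same days) and of the signed wait
    disparity (%); ``per_day`` keeps the day-level values."""

    table: pd.DataFrame
    per_day: pd.DataFrame

    def summary_text(self) -> str:
        lines = ["method comparison (mean ± MC standard error over days)", ""]
        for row in self.table.itertuples():
            gap = (
                f"{row.mean_gap:8.2f} ± {row.se_gap:5.2f} %"
                if not np.isnan(row.mean_gap)
                else "     n/a"
            )
            lines.append(
                f"{row.method:<14s} optimality gap {gap}   "
                f"disparity {row.mean_disparity:8.2f} ± {row.se_disparity:5.2f} %"
            )
        return "\n".join(lines) + "\n"


def fit_method_models(
    config: ExperimentConfig, seed: int
) -> dict[Regime, ShowModel]:
    """Fit one show model per regime needed, on a training population."""
    pop_cfg = replace(config.population, n_patients=config.n_train, seed=seed)
    roster = generate_population(pop_cfg)
    history = generate_history(roster, pop_cfg.history_length, seed + 1)
    regimes = {METHODS[m].regime for m in config.methods}
    return {r: fit_show_model(history, roster, r) for r in regimes}


def _draw_day_roster(
    config: ExperimentConfig, rng: np.random.Generator
) -> tuple[Roster, pd.DataFrame]:
    """Draw a day roster containing both groups (resampling a bounded
    number of times — disparity is undefined on one-group days)."""
    for _ in range(200):
        seed = int(rng.integers(2**31))
        cfg = replace(config.population, n_patients=config.n_patients, seed=seed)
        roster = generate_population(cfg)
        if len(roster.group_labels()) >= 2:
            history = generate_history(
                roster, config.population.history_length, seed + 1
            )
            return attach_history_features(roster, history), history
    raise ConfigurationError(
        "could not draw a two-group day roster; fraction_group_b too extreme "
        "for this roster size"
    )


def run_comparison(config: ExperimentConfig) -> ComparisonTable:
    """Run the replicated-day comparison and aggregate with standard errors."""
    grid = SlotGrid(
        n_slots=config.n_slots,
        slot_duration=config.slot_duration,
        capacity=config.capacity,
    )
    rng = np.random.default_rng(config.master_seed)
    train_seed = int(rng.integers(2**31))
    models = fit_method_models(config, train_seed)
    want_gap = "SOTA" in config.methods
    records = []
    for day in range(config.n_days):
        roster, _history = _draw_day_roster(config, rng)
        true_probs = roster.show_probs()
        day_costs: dict[str, float] = {}
        day_rows = []
        for name in config.methods:
            method = METHODS[name]
            preds = predict_roster(models[method.regime], roster)
            spec = ObjectiveSpec(variant=method.variant, weights=config.weights)
            opt_seed = int(rng.integers(2**31))
            try:
                assignment = optimize_heuristic(
                    roster,
                    grid,
                    preds,
                    spec,
                    seed=opt_seed,
                    n_starts=config.heuristic_starts,
                    max_iters=config.heuristic_iters,
                    n_kicks=config.heuristic_kicks,
                )
                outcome = expected_outcome_exact(assignment, grid, true_probs)
            except Exception as exc:  # surface the failing stage
                raise RuntimeError(
                    f"day {day}, method {name}: {exc}"
                ) from exc
            cost = schedule_cost(outcome, config.weights)
            disparity = wait_disparity(
                outcome, roster, config.protected_group, show_probs=true_probs
            )
            sums = group_wait_show_sums(outcome.expected_wait, roster, true_probs)
            wp, sp = sums.get(config.protected_group, (0.0, 0.0))
            wo = sum(w for g, (w, _) in sums.items() if g != config.protected_group)
            so = sum(q for g, (_, q) in sums.items() if g != config.protected_group)
            day_costs[name] = cost
            day_rows.append(
                {
                    "day": day,
                    "method": name,
                    "cost": cost,
                    "disparity": disparity,
                    "wait_prot": wp,
                    "show_prot": sp,
                    "wait_other": wo,
                    "show_other": so,
                }
            )
        for row in day_rows:
            row["gap"] = (
                100.0 * (row["cost"] - day_costs["SOTA"]) / day_costs["SOTA"]
                if want_gap
                else np.nan
            )
        records.extend(day_rows)
    per_day = pd.DataFrame(records)
    rows = []
    for name in config.methods:
        sub = per_day[per_day["method"] == name]
        nd = len(sub)
        se = (lambda s: float(s.std(ddof=1) / np.sqrt(nd)) if nd > 1 else 0.0)
        disp, disp_se = _pooled_disparity(sub)
        rows.append(
            {
                "method": name,
                "mean_gap": float(sub["gap"].mean()),
                "se_gap": se(sub["gap"]),
                "mean_disparity": disp,
                "se_disparity": disp_se,
                "mean_cost": float(sub["cost"].mean()),
                "n_days": nd,
            }
        )
    return ComparisonTable(table=pd.DataFrame(rows), per_day=per_day)


def _pooled_disparity(sub: pd.DataFrame) -> tuple[float, float]:
    """Disparity of the pooled multi-day population, with a
    delete-one-day jackknife standard error."""
    wp = sub["wait_prot"].to_numpy()
    sp = sub["show_prot"].to_numpy()
    wo = sub["wait_other"].to_numpy()
    so = sub["show_other"].to_numpy()
    point = disparity_from_sums(wp.sum(), sp.sum(), wo.sum(), so.sum())
    nd = len(wp)
    if nd < 2:
        return point, 0.0
    loo = np.array(
        [
            disparity_from_sums(
                wp.sum() - wp[d], sp.sum() - sp[d], wo.sum() - wo[d], so.sum() - so[d]
            )
            for d in range(nd)
        ]
    )
    se = float(np.sqrt((nd - 1) / nd * ((loo - loo.mean()) ** 2).sum()))
    return point, se
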