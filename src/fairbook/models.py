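"""Show-probability models under three feature regimes.

FULL uses every feature (socio-economic plus attendance-history
summaries), NO_SES uses history summaries only, and NONE fits no model
at all — every patient receives the overall population show rate.  The
three regimes are the machine-learning intervention menu: keep the
predictor, strip its group-correlated socio-economic inputs, or remove
it entirely.

The learner is plain (unpenalized) logistic regression.  Training rows
are individual past visits; the history-summary features of a row are
computed leave-one-out (from the patient's *other* visits) so the
outcome visit never summarizes itself.  Zero-variance training columns
(e.g. the past-visit count when every patient has the same history
length) are dropped before fitting and recorded on the model.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .core import HISTORY_FEATURE_NAMES, PatientRecord, Roster
from .errors import FitError, MissingFeatureError

HISTORY_SUMMARY_FEATURES = list(HISTORY_FEATURE_NAMES)  # past_show_count, past_visit_count


class Regime(str, enum.Enum):
    FULL = "FULL"
    NO_SES = "NO_SES"
    NONE = "NONE"


@dataclass(frozen=True)
class ShowModel:
    """A fitted show-probability predictor.

    FULL/NO_SES carry logistic coefficients over ``feature_names``;
    NONE carries only ``population_rate``.  ``dropped_features`` lists
    training columns removed for zero variance (predictions are
    invariant to them).
    """

    regime: Regime
    intercept: float = 0.0
    coef: dict[str, float] = field(default_factory=dict)
    population_rate: float | None = None
    dropped_features: tuple[str, ...] = ()

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def to_json(self) -> str:
        return json.dumps(
            {
                "regime": self.regime.value,
                "intercept": self.intercept,
                "coef": self.coef,
                "population_rate": self.population_rate,
                "dropped_features": list(self.dropped_features),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ShowModel":
        d = json.loads(text)
        return cls(
            regime=Regime(d["regime"]),
            intercept=float(d["intercept"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            population_rate=(
                None if d["population_rate"] is None else float(d["population_rate"])
            ),
            dropped_features=tuple(d["dropped_features"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ShowModel":
        return cls.from_json(Path(path).read_text())


def _regime_feature_names(regime: Regime, roster: Roster) -> list[str]:
    ses: list[str] = []
    if regime == Regime.FULL:
        for p in roster:
            for name in p.ses:
                if name not in ses:
                    ses.append(name)
        ses.sort()
    return ses + HISTORY_SUMMARY_FEATURES


def fit_show_model(
    history: pd.DataFrame, roster: Roster, regime: Regime
) -> ShowModel:
    """Fit a show model on an appointment-history table.

    ``history`` needs columns ``patient_id`` and ``show`` (0/1).  NONE
    reduces to the overall mean show rate; FULL/NO_SES are logistic fits
    of the visit outcome on the regime's feature set plus leave-one-out
    history summaries.  A history that is empty, or in which every visit
    has the same outcome, cannot be fitted.
    """
    if len(history) == 0:
        raise FitError("cannot fit a show model on an empty history")
    y = history["show"].to_numpy(dtype=float)
    rate = float(y.mean())
    if regime == Regime.NONE:
        return ShowModel(regime=Regime.NONE, population_rate=rate)
    if rate in (0.0, 1.0):
        raise FitError(
            "degenerate history: every recorded visit has the same outcome "
            f"(show rate {rate:.0f}); a logistic model cannot be fitted"
        )
    by_id = {p.patient_id: p for p in roster}
    unknown = set(history["patient_id"]) - set(by_id)
    if unknown:
        raise FitError(f"history references patients not on the roster: {sorted(unknown)}")
    totals = history.groupby("patient_id")["show"].agg(["sum", "size"])
    tot_shows = totals["sum"].to_dict()
    tot_visits = totals["size"].to_dict()
    names = _regime_feature_names(regime, roster)
    rows = np.empty((len(history), len(names)))
    pid_col = history["patient_id"].to_numpy()
    for j, name in enumerate(names):
        if name == "past_show_count":
            rows[:, j] = np.array([tot_shows[pid] for pid in pid_col], float) - y
        elif name == "past_visit_count":
            rows[:, j] = [tot_visits[pid] - 1 for pid in pid_col]
        else:
            try:
                rows[:, j] = [by_id[pid].ses[name] for pid in pid_col]
            except KeyError as exc:
                raise MissingFeatureError(
                    f"roster patient lacks SES feature {name!r}"
                ) from exc
    keep = [j for j in range(len(names)) if np.ptp(rows[:, j]) > 0]
    dropped = tuple(names[j] for j in range(len(names)) if j not in keep)
    if not keep:
        raise FitError("all candidate features are constant; nothing to fit")
    # C=inf -> unpenalized maximum-likelihood fit
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    lr.fit(rows[:, keep], y)
    coef = {names[j]: float(c) for j, c in zip(keep, lr.coef_[0])}
    return ShowModel(
        regime=regime,
        intercept=float(lr.intercept_[0]),
        coef=coef,
        population_rate=rate,
        dropped_features=dropped,
    )


def predict_show_prob(model: ShowModel, patient: PatientRecord) -> float:
    """Predicted show probability for one patient, in [0, 1]."""
    if model.regime == Regime.NONE:
        if model.population_rate is None:
            raise FitError("NONE model lacks a population rate")
        return model.population_rate
    z = model.intercept
    merged = {**patient.ses, **patient.history}
    for name, c in model.coef.items():
        if name not in merged:
            raise MissingFeatureError(
                f"patient {patient.patient_id!r} lacks feature {name!r} "
                f"required by the {model.regime.value} model"
            )
        z += c * float(merged[name])
    return 1.0 / (1.0 + math.exp(-z))


def predict_roster(model: ShowModel, roster: Roster) -> dict[str, float]:
    """patient_id -> predicted show probability for a whole roster."""
    return {p.patient_id: predict_show_prob(model, p) for p in roster}
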