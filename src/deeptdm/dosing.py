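"""Regimen simulation and dose-interval recommendation.

Two clinician-facing functions sit on top of the trough predictor:

* ``simulate_regimen`` appends hypothetical future doses to a patient's
  history (covariates carried forward) and predicts the trough at each
  appended administration, allowing a different dose/interval at every
  future time point;
* ``recommend`` scores a fixed menu of (interval, per-kg dose)
  combinations — general ICU patients: {8, 12, 18, 24, 48} h ×
  {15..20} mg/kg; dialysis patients: 12 h × {7.5..10 in 0.5} mg/kg —
  by simulating several repeated cycles of each regimen (steady-state
  approximation) and keeps the combinations whose predicted trough lands
  in the therapeutic window [15, 20] μg/mL.

The menus print dose increments per kilogram of body weight (mg/kg).
Predictors are callables mapping a :class:`PatientCourse` to a list of
per-dose trough predictions, so a trained model, a PK formula, or a stub
can all drive the same machinery; ``model_predictor`` adapts a trained
checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .model import GointMLP, predict_course
from .pk import DoseEvent, PatientCourse, PkCoefficients
from .preprocessing import ScalerState

__all__ = [
    "THERAPEUTIC_RANGE",
    "RegimenCandidate",
    "candidate_grid",
    "model_predictor",
    "simulate_regimen",
    "score_grid",
    "recommend",
]

THERAPEUTIC_RANGE: tuple[float, float] = (15.0, 20.0)

_GENERAL_INTERVALS = (8.0, 12.0, 18.0, 24.0, 48.0)
_GENERAL_DOSES = (15.0, 16.0, 17.0, 18.0, 19.0, 20.0)
_DIALYSIS_INTERVALS = (12.0,)
_DIALYSIS_DOSES = (7.5, 8.0, 8.5, 9.0, 9.5, 10.0)

Predictor = Callable[[PatientCourse], list[float]]


@dataclass(frozen=True)
class RegimenCandidate:
    """A scored (interval, per-kg dose) combination."""

    interval_h: float
    dose_per_kg: float
    absolute_dose_mg: float
    predicted_trough: float
    in_range: bool


def candidate_grid(dialysis: bool) -> list[tuple[float, float]]:
    """(interval h, dose mg/kg) menu: 30 general or 6 dialysis candidates."""
    if dialysis:
        return [(i, d) for i in _DIALYSIS_INTERVALS for d in _DIALYSIS_DOSES]
    return [(i, d) for i in _GENERAL_INTERVALS for d in _GENERAL_DOSES]


def model_predictor(
    model: GointMLP, scaler: ScalerState, coeffs: PkCoefficients = PkCoefficients()
) -> Predictor:
    """Adapt a trained model + scaler into a course → troughs callable."""

    def predict(course: PatientCourse) -> list[float]:
        return [r.y_reg for r in predict_course(model, course, scaler, coeffs)]

    return predict


def extend_course(
    course: PatientCourse, future: Sequence[tuple[float, float]]
) -> PatientCourse:
    """Append hypothetical (dose_mg, interval_h) events, covariates carried forward."""
    if not future:
        raise ValueError("future dose list is empty")
    if not course.dose_events:
        raise ValueError("cannot extend a course with no dose history")
    events = list(course.dose_events)
    # stored per-event cumulatives may be unset (0); fall back to the sum
    cumulative = max(
        max(e.cumulative_dose_mg for e in events),
        sum(e.dose_mg for e in events),
    )
    t = events[-1].time
    for dose_mg, interval_h in future:
        if interval_h <= 0:
            raise ValueError("future intervals must be positive")
        t += interval_h
        cumulative += dose_mg
        events.append(
            DoseEvent(
                time=t,
                dose_mg=dose_mg,
                admin_time=max(1.0, dose_mg / 1000.0),
                interval_h=interval_h,
                loading=0,
                cumulative_dose_mg=cumulative,
            )
        )
    return replace(course, dose_events=events)


def simulate_regimen(
    predictor: Predictor,
    course: PatientCourse,
    future: Sequence[tuple[float, float]],
) -> list[float]:
    """Predicted troughs at each appended future (dose_mg, interval_h) event.

    Dose and interval may differ at every future time point.  The
    sequential module is causal, so predictions at historical events are
    unchanged by the appended futures.
    """
    extended = extend_course(course, future)
    preds = predictor(extended)
    return preds[len(course.dose_events):]


def score_grid(
    predictor: Predictor,
    course: PatientCourse,
    weight: float,
    dialysis: bool,
    steady_state_cycles: int = 4,
    therapeutic_range: tuple[float, float] = THERAPEUTIC_RANGE,
) -> list[RegimenCandidate]:
    """Score every menu combination by its predicted steady-state trough.

    Each candidate is simulated as ``steady_state_cycles`` repeated
    identical future doses; the trough read at the last cycle approximates
    steady state (the caller asserts the patient is near steady state).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if steady_state_cycles < 1:
        raise ValueError("need at least one simulated cycle")
    lo, hi = therapeutic_range
    out = []
    for interval_h, dose_per_kg in candidate_grid(dialysis):
        dose_mg = dose_per_kg * weight
        troughs = simulate_regimen(
            predictor, course, [(dose_mg, interval_h)] * steady_state_cycles
        )
        trough = float(troughs[-1])
        out.append(
            RegimenCandidate(
                interval_h=interval_h,
                dose_per_kg=dose_per_kg,
                absolute_dose_mg=dose_mg,
                predicted_trough=trough,
                in_range=lo <= trough <= hi,
            )
        )
    return out


def recommend(
    predictor: Predictor,
    course: PatientCourse,
    weight: float,
    dialysis: bool,
    steady_state_cycles: int = 4,
    therapeutic_range: tuple[float, float] = THERAPEUTIC_RANGE,
) -> list[RegimenCandidate]:
    """The menu combinations whose predicted steady-state trough is in range.

    May be empty when no combination reaches the therapeutic window; the
    full scored grid is available through :func:`score_grid`.
    """
    return [
        c
        for c in score_grid(
            predictor, course, weight, dialysis, steady_state_cycles, therapeutic_range
        )
        if c.in_range
    ]
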