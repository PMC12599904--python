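"""Renal-function and pharmacokinetic covariates for vancomycin dosing events.

Every dosing event is summarised by sixteen covariates: four demographics
(sex, age, height, weight), the dosing context (interval since the previous
dose, time from injection to the TDM blood draw, loading-dose flag, dialysis
status, infusion duration, dose per infusion, cumulative dose), the latest
serum creatinine, and four derived renal/PK quantities (MDRD eGFR,
Cockcroft-Gault-based vancomycin clearance, average volume of distribution,
elimination rate constant).  The derived quantities are recomputed at every
dosing time point from the most recent creatinine available (forward fill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "BINARY_FEATURES",
    "DoseEvent",
    "TdmMeasurement",
    "PatientCourse",
    "PkCoefficients",
    "crcl_cockcroft_gault",
    "vancomycin_clearance",
    "egfr_mdrd",
    "volume_of_distribution",
    "elimination_rate_constant",
    "build_feature_sequence",
    "MissingCreatinineError",
]

#: Canonical ordering of the 16 covariates; feature matrices follow this order.
FEATURE_NAMES: tuple[str, ...] = (
    "sex",
    "age",
    "height",
    "weight",
    "interval_h",
    "time_to_draw_h",
    "loading",
    "dialysis",
    "scr",
    "avg_volume_of_distribution",
    "elimination_rate_constant",
    "admin_time_h",
    "dose_mg",
    "cumulative_dose_mg",
    "egfr_mdrd",
    "vancomycin_clearance",
)

#: Binary covariates kept in raw {0,1} form by the scaler (loading, dialysis).
BINARY_FEATURES: tuple[str, ...] = ("loading", "dialysis")


class MissingCreatinineError(ValueError):
    """No serum creatinine is available at or before the first dose."""


@dataclass(frozen=True)
class DoseEvent:
    """A single vancomycin administration.

    ``time`` is hours from course start; ``admin_time`` is the infusion
    duration in hours (0 is treated as an instantaneous bolus);
    ``interval_h`` is the gap since the previous dose and 0.0 for the
    first dose of a course (documented convention — the event is kept).
    """

    time: float
    dose_mg: float
    admin_time: float = 1.0
    interval_h: float = 0.0
    loading: int = 0
    cumulative_dose_mg: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError(f"dose_mg must be positive, got {self.dose_mg}")
        if self.admin_time < 0:
            raise ValueError("admin_time must be nonnegative")


@dataclass(frozen=True)
class TdmMeasurement:
    """A measured vancomycin trough (μg/mL) with its draw time."""

    time: float
    trough_ug_ml: float
    time_since_dose_h: float

    def __post_init__(self) -> None:
        if self.trough_ug_ml < 0:
            raise ValueError("trough_ug_ml must be nonnegative")
        if self.time_since_dose_h < 0:
            raise ValueError("time_since_dose_h must be nonnegative")


@dataclass
class PatientCourse:
    """One independent vancomycin treatment course.

    ``sex`` is ``"male"`` or ``"female"``; times are hours from course
    start and must be strictly increasing within each list.
    """

    patient_id: str
    sex: str
    age: float
    height: float
    weight: float
    dialysis: int
    creatinine_series: list[tuple[float, float]] = field(default_factory=list)
    dose_events: list[DoseEvent] = field(default_factory=list)
    tdm_measurements: list[TdmMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 18:
            raise ValueError("age must exceed 18 years (adult ICU population)")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("height and weight must be positive")
        for series in (
            [t for t, _ in self.creatinine_series],
            [d.time for d in self.dose_events],
            [m.time for m in self.tdm_measurements],
        ):
            if any(b <= a for a, b in zip(series, series[1:])):
                raise ValueError("event times must be strictly increasing")
        if self.dose_events:
            first = self.dose_events[0].time
            for m in self.tdm_measurements:
                if m.time <= first:
                    raise ValueError("TDM draw precedes every dose event")


@dataclass(frozen=True)
class PkCoefficients:
    """Configurable coefficients of the derived PK covariates.

    ``vd_per_kg`` — average volume of distribution per body weight
    (L/kg, default 0.7, the textbook adult vancomycin value);
    ``mdrd_constant`` — leading coefficient of the re-expressed
    4-variable MDRD equation; ``mdrd_female`` — female sex factor.
    """

    vd_per_kg: float = 0.7
    mdrd_constant: float = 175.0
    mdrd_female: float = 0.742


def _sex_factor(sex: str) -> float:
    if sex == "male":
        return 1.0
    if sex == "female":
        return 0.85
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def crcl_cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Cockcroft–Gault creatinine clearance in mL/min.

    CrCl = (140 − age) · weight · K / (72 · Scr), with K = 1.0 for males
    and 0.85 for females.
    """
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if weight <= 0:
        raise ValueError("weight must be positive")
    if age > 140:
        raise ValueError("age above 140 years is outside the formula's domain")
    return (140.0 - age) * weight * _sex_factor(sex) / (72.0 * scr)


def vancomycin_clearance(crcl: float, weight: float) -> float:
    """Vancomycin clearance (L/h) linear in creatinine clearance.

    CL = (0.695 · CrCl/weight + 0.05) · weight · 0.06; the 0.06 factor
    converts mL/min to L/h and the 0.05 intercept is the non-renal floor.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if crcl < 0:
        raise ValueError("creatinine clearance must be nonnegative")
    return (0.695 * crcl / weight + 0.05) * weight * 0.06


def egfr_mdrd(
    scr: float, age: float, sex: str, coeffs: PkCoefficients = PkCoefficients()
) -> float:
    """Estimated GFR (mL/min/1.73 m²), 4-variable re-expressed MDRD.

    eGFR = 175 · Scr^−1.154 · age^−0.203 · (0.742 if female).  The race
    coefficient is omitted: race is not among the model covariates.
    """
    if scr <= 0 or age <= 0:
        raise ValueError("scr and age must be positive")
    factor = coeffs.mdrd_female if sex == "female" else 1.0
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return coeffs.mdrd_constant * scr**-1.154 * age**-0.203 * factor


def volume_of_distribution(
    weight: float, coeffs: PkCoefficients = PkCoefficients()
) -> float:
    """Average volume of distribution (L): ``vd_per_kg`` × body weight."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return coeffs.vd_per_kg * weight


def elimination_rate_constant(cl: float, vd: float) -> float:
    """First-order elimination rate constant ke = CL / Vd (1/h)."""
    if vd <= 0:
        raise ValueError("volume of distribution must be positive")
    if cl < 0:
        raise ValueError("clearance must be nonnegative")
    return cl / vd


def _scr_at(course: PatientCourse, t: float) -> float:
    """Latest creatinine at or before t (forward fill)."""
    latest = None
    for time, scr in course.creatinine_series:
        if time <= t:
            latest = scr
        else:
            break
    if latest is None:
        raise MissingCreatinineError(
            f"course {course.patient_id}: no creatinine at or before t={t:g} h"
        )
    return latest


def _tdm_for_dose(course: PatientCourse, idx: int) -> TdmMeasurement | None:
    """The TDM draw attached to dose ``idx`` (latest dose preceding the draw)."""
    doses = course.dose_events
    for m in course.tdm_measurements:
        preceding = None
        for j, d in enumerate(doses):
            if d.time < m.time:
                preceding = j
        if preceding == idx:
            return m
    return None


def build_feature_sequence(
    course: PatientCourse, coeffs: PkCoefficients = PkCoefficients()
) -> np.ndarray:
    """One 16-covariate row per dose event, in time order.

    Creatinine and all derived PK covariates at event t use the most recent
    creatinine measurement at or before t.  ``time_to_draw_h`` is the actual
    injection-to-draw delay when a TDM measurement is attached to the event,
    and otherwise the gap to the next dose (the horizon at which a trough
    would be drawn); the last event falls back to its own interval.

    Raises :class:`MissingCreatinineError` when no creatinine can be carried
    forward to the first dose — callers exclude such records.
    """
    if not course.dose_events:
        return np.empty((0, len(FEATURE_NAMES)))
    sex = 1.0 if course.sex == "male" else 0.0
    vd = volume_of_distribution(course.weight, coeffs)
    rows = []
    running = 0.0
    doses = course.dose_events
    for i, d in enumerate(doses):
        running += d.dose_mg
        scr = _scr_at(course, d.time)
        crcl = crcl_cockcroft_gault(course.age, course.weight, scr, course.sex)
        cl = vancomycin_clearance(crcl, course.weight)
        ke = elimination_rate_constant(cl, vd)
        egfr = egfr_mdrd(scr, course.age, course.sex, coeffs)
        tdm = _tdm_for_dose(course, i)
        if tdm is not None:
            draw = tdm.time - d.time
        elif i + 1 < len(doses):
            draw = doses[i + 1].time - d.time
        else:
            draw = d.interval_h
        cumulative = d.cumulative_dose_mg if d.cumulative_dose_mg > 0 else running
        rows.append(
            [
                sex,
                course.age,
                course.height,
                course.weight,
                d.interval_h,
                draw,
                float(d.loading),
                float(course.dialysis),
                scr,
                vd,
                ke,
                d.admin_time,
                d.dose_mg,
                cumulative,
                egfr,
                cl,
            ]
        )
    out = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite covariate produced from course data")
    return out
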