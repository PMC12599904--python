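"""Course tables on disk, run configuration, and reproducibility plumbing.

The on-disk course format is a tidy CSV with one row per event:

====================  =========================================================
column                meaning
====================  =========================================================
patient_id            opaque course identifier
sex, age, height,     patient covariates, repeated on every row of the course
weight, dialysis
time_h                event time in hours from course start
event_type            ``dose``, ``scr`` or ``tdm``
dose_mg               dose rows: amount administered (mg)
admin_time_h          dose rows: infusion duration (h)
interval_h            dose rows: hours since the previous dose (0 for first)
loading               dose rows: loading-dose flag {0,1}
scr_mg_dl             scr rows: serum creatinine (mg/dL)
trough_ug_ml          tdm rows: measured trough (μg/mL)
time_since_dose_h     tdm rows: injection-to-draw delay (h)
====================  =========================================================

Malformed rows or courses (negative doses, non-monotone times, missing
covariates) are collected into a rejection report instead of being
silently dropped.  JSON round-trips a single course verbatim.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .pk import DoseEvent, PatientCourse, TdmMeasurement

__all__ = [
    "write_courses",
    "read_courses",
    "read_courses_with_report",
    "course_to_json",
    "course_from_json",
    "load_run_config",
    "config_hash",
]

_COLUMNS = [
    "patient_id", "sex", "age", "height", "weight", "dialysis",
    "time_h", "event_type", "dose_mg", "admin_time_h", "interval_h",
    "loading", "scr_mg_dl", "trough_ug_ml", "time_since_dose_h",
]


def write_courses(courses: list[PatientCourse], path: str | Path) -> None:
    """Write courses to the tidy CSV format."""
    rows = []
    for c in courses:
        base = {
            "patient_id": c.patient_id, "sex": c.sex, "age": c.age,
            "height": c.height, "weight": c.weight, "dialysis": c.dialysis,
        }
        for t, s in c.creatinine_series:
            rows.append({**base, "time_h": t, "event_type": "scr", "scr_mg_dl": s})
        for d in c.dose_events:
            rows.append(
                {**base, "time_h": d.time, "event_type": "dose", "dose_mg": d.dose_mg,
                 "admin_time_h": d.admin_time, "interval_h": d.interval_h,
                 "loading": d.loading}
            )
        for m in c.tdm_measurements:
            rows.append(
                {**base, "time_h": m.time, "event_type": "tdm",
                 "trough_ug_ml": m.trough_ug_ml,
                 "time_since_dose_h": m.time_since_dose_h}
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.sort_values(["patient_id", "time_h"], kind="stable").to_csv(path, index=False)


def _build_course(pid: str, group: pd.DataFrame) -> PatientCourse:
    first = group.iloc[0]
    doses, scr, tdm = [], [], []
    cumulative = 0.0
    for _, row in group.sort_values("time_h", kind="stable").iterrows():
        kind = row["event_type"]
        if kind == "dose":
            if row["dose_mg"] <= 0:
                raise ValueError(f"negative or zero dose at t={row['time_h']}")
            cumulative += float(row["dose_mg"])
            doses.append(
                DoseEvent(
                    time=float(row["time_h"]),
                    dose_mg=float(row["dose_mg"]),
                    admin_time=float(row["admin_time_h"]),
                    interval_h=float(row["interval_h"]),
                    loading=int(row["loading"]),
                    cumulative_dose_mg=cumulative,
                )
            )
        elif kind == "scr":
            scr.append((float(row["time_h"]), float(row["scr_mg_dl"])))
        elif kind == "tdm":
            tdm.append(
                TdmMeasurement(
                    time=float(row["time_h"]),
                    trough_ug_ml=float(row["trough_ug_ml"]),
                    time_since_dose_h=float(row["time_since_dose_h"]),
                )
            )
        else:
            raise ValueError(f"unknown event_type {kind!r}")
    return PatientCourse(
        patient_id=str(pid),
        sex=str(first["sex"]),
        age=float(first["age"]),
        height=float(first["height"]),
        weight=float(first["weight"]),
        dialysis=int(first["dialysis"]),
        creatinine_series=scr,
        dose_events=doses,
        tdm_measurements=tdm,
    )


def read_courses_with_report(path: str | Path) -> tuple[list[PatientCourse], list[dict]]:
    """Read the tidy CSV; invalid courses land in the rejection report.

    Returns (courses, rejections) where each rejection is a dict with the
    offending ``patient_id`` and the validation ``reason``.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no course rows found", stacklevel=2)
        return [], []
    unknown = set(df.columns) - set(_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    missing = {"patient_id", "time_h", "event_type"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    courses, rejections = [], []
    for pid, group in df.groupby("patient_id", sort=True):
        try:
            courses.append(_build_course(str(pid), group))
        except (ValueError, KeyError) as exc:
            rejections.append({"patient_id": str(pid), "reason": str(exc)})
    return courses, rejections


def read_courses(path: str | Path) -> list[PatientCourse]:
    """Read courses, warning about (but not raising on) rejected courses."""
    courses, rejections = read_courses_with_report(path)
    if rejections:
        warnings.warn(
            f"{path}: excluded {len(rejections)} invalid course(s): "
            + "; ".join(f"{r['patient_id']}: {r['reason']}" for r in rejections[:5]),
            stacklevel=2,
        )
    return courses


def course_to_json(course: PatientCourse) -> str:
    d = asdict(course)
    d["creatinine_series"] = [list(p) for p in d["creatinine_series"]]
    return json.dumps(d, sort_keys=True)


def course_from_json(text: str) -> PatientCourse:
    d = json.loads(text)
    return PatientCourse(
        patient_id=d["patient_id"],
        sex=d["sex"],
        age=d["age"],
        height=d["height"],
        weight=d["weight"],
        dialysis=d["dialysis"],
        creatinine_series=[tuple(p) for p in d["creatinine_series"]],
        dose_events=[DoseEvent(**e) for e in d["dose_events"]],
        tdm_measurements=[TdmMeasurement(**m) for m in d["tdm_measurements"]],
    )


def load_run_config(path: str | Path | None) -> dict:
    """Load the (optional) YAML run configuration; missing path → {}."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of an effective configuration, for run logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
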