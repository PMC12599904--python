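"""Sequence preprocessing: scaling, ordinal targets, masking, padding.

Troughs are bucketed into three ordered ranges — sub-therapeutic
(< 15 μg/mL), therapeutic (15–20 μg/mL) and toxic (> 20 μg/mL) — and
encoded as K−1 = 2 cumulative binary labels ("is the trough above 15?",
"is it above 20?").  Continuous covariates are min–max scaled to [−1, 1]
on the training split only; the loading and dialysis flags stay {0,1}.
Training sequences are truncated to the configured maximum length (most
recent events kept); evaluation sequences are never truncated.  The mask
marks the dose events at which an actual TDM trough was drawn — the loss
and all metrics only ever look at masked-in steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pk import BINARY_FEATURES, FEATURE_NAMES, PatientCourse, build_feature_sequence
from .pk import MissingCreatinineError, PkCoefficients, egfr_mdrd

__all__ = [
    "CLASS_NAMES",
    "ORDINAL_THRESHOLDS",
    "ScalerState",
    "SequenceBatch",
    "encode_ordinal",
    "decode_ordinal",
    "trough_class",
    "split_independent_courses",
    "assemble_batches",
    "DegenerateScaleError",
]

ORDINAL_THRESHOLDS: tuple[float, float] = (15.0, 20.0)
CLASS_NAMES: tuple[str, str, str] = ("sub", "therapeutic", "toxic")

#: Sentinel written into target arrays at steps without a TDM draw.
TARGET_SENTINEL = np.nan


class DegenerateScaleError(ValueError):
    """A continuous variable is constant on the training split."""


def trough_class(trough: float, thresholds: tuple[float, float] = ORDINAL_THRESHOLDS) -> int:
    """3-range class of a trough: 0 sub, 1 therapeutic, 2 toxic.

    Endpoints go to the therapeutic range: exactly 15 and exactly 20 are
    therapeutic (the toxic range is strictly > 20).
    """
    if trough < 0:
        raise ValueError("trough must be nonnegative")
    lo, hi = thresholds
    if trough < lo:
        return 0
    if trough <= hi:
        return 1
    return 2


def encode_ordinal(
    trough: float, thresholds: tuple[float, float] = ORDINAL_THRESHOLDS
) -> np.ndarray:
    """Cumulative binary encoding of the 3-range trough class.

    sub → [0,0]; therapeutic → [1,0]; toxic → [1,1].
    """
    c = trough_class(trough, thresholds)
    return np.asarray([1.0 if c >= 1 else 0.0, 1.0 if c >= 2 else 0.0])


def decode_ordinal(binaries: np.ndarray) -> int:
    """Class index recovered from cumulative binaries (rank = count of ones)."""
    b = np.asarray(binaries)
    if b.shape[-1] != 2:
        raise ValueError("expected 2 threshold binaries")
    return int(b[0] > 0.5) + int((b[0] > 0.5) and (b[1] > 0.5))


@dataclass
class ScalerState:
    """Per-variable [−1, 1] min–max scaling fitted on the training split.

    Binary variables (loading, dialysis) pass through unscaled.  The state
    serialises to JSON so stored checkpoints reproduce predictions exactly.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    binary_idx: list[int]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.maxs - self.mins
        out = 2.0 * (x - self.mins) / span - 1.0
        out[..., self.binary_idx] = x[..., self.binary_idx]
        return out

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        span = self.maxs - self.mins
        out = (z + 1.0) / 2.0 * span + self.mins
        out[..., self.binary_idx] = z[..., self.binary_idx]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "mins": self.mins.tolist(),
                "maxs": self.maxs.tolist(),
                "binary_idx": self.binary_idx,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerState":
        d = json.loads(text)
        return cls(
            feature_names=list(d["feature_names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            binary_idx=list(d["binary_idx"]),
        )

    @classmethod
    def fit(
        cls,
        training_features: np.ndarray,
        feature_names: tuple[str, ...] = FEATURE_NAMES,
        binary_features: tuple[str, ...] = BINARY_FEATURES,
    ) -> "ScalerState":
        """Fit mins/maxs on stacked training rows [n × n_features]."""
        x = np.asarray(training_features, dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 training rows")
        binary_idx = [feature_names.index(b) for b in binary_features]
        mins = x.min(axis=0)
        maxs = x.max(axis=0)
        for j, name in enumerate(feature_names):
            if j in binary_idx:
                # keep a unit span so transform stays finite even if unused
                mins[j], maxs[j] = 0.0, 1.0
                continue
            if maxs[j] <= mins[j]:
                raise DegenerateScaleError(
                    f"variable {name!r} is constant on the training split"
                )
        return cls(list(feature_names), mins, maxs, binary_idx)


def split_independent_courses(
    history: PatientCourse,
    gap_h: float = 14 * 24.0,
    normal_egfr: float = 60.0,
    coeffs: PkCoefficients = PkCoefficients(),
) -> list[PatientCourse]:
    """Split a patient history into independent treatment courses.

    A new course starts at a dose separated by at least ``gap_h`` (default
    14 days) from the previous dose, provided the patient's renal function
    is normal at the gap — latest MDRD eGFR ≥ ``normal_egfr``
    (mL/min/1.73 m², default 60).  Creatinine and TDM records are assigned
    to the course whose dose span contains them; course-internal times are
    re-zeroed at each course's first dose.
    """
    doses = history.dose_events
    if len(doses) < 2:
        return [history]
    boundaries = [0]
    for i in range(1, len(doses)):
        if doses[i].time - doses[i - 1].time >= gap_h:
            scr = None
            for t, s in history.creatinine_series:
                if t <= doses[i].time:
                    scr = s
            if scr is not None and egfr_mdrd(scr, history.age, history.sex, coeffs) >= normal_egfr:
                boundaries.append(i)
    if len(boundaries) == 1:
        return [history]
    courses = []
    spans = list(zip(boundaries, boundaries[1:] + [len(doses)]))
    for n, (a, b) in enumerate(spans):
        t0 = doses[a].time
        t_end = doses[b].time if b < len(doses) else np.inf
        sub_doses = []
        for k in range(a, b):
            d = doses[k]
            sub_doses.append(
                type(d)(
                    time=d.time - t0,
                    dose_mg=d.dose_mg,
                    admin_time=d.admin_time,
                    interval_h=d.interval_h if k > a else 0.0,
                    loading=d.loading,
                    cumulative_dose_mg=0.0,
                )
            )
        # keep the latest pre-course creatinine, re-timed to the course start
        pre = [(t, s) for t, s in history.creatinine_series if t <= doses[a].time]
        within = [(t - t0, s) for t, s in history.creatinine_series if doses[a].time < t < t_end]
        scr = ([(0.0, pre[-1][1])] if pre else []) + within
        tdm = [
            type(m)(m.time - t0, m.trough_ug_ml, m.time_since_dose_h)
            for m in history.tdm_measurements
            if doses[a].time < m.time and m.time < t_end
        ]
        courses.append(
            PatientCourse(
                patient_id=f"{history.patient_id}-c{n}",
                sex=history.sex,
                age=history.age,
                height=history.height,
                weight=history.weight,
                dialysis=history.dialysis,
                creatinine_series=scr,
                dose_events=sub_doses,
                tdm_measurements=tdm,
            )
        )
    return courses


@dataclass
class SequenceBatch:
    """Padded, masked, scaled training/evaluation sequences.

    ``features``: [batch × T × 16] scaled covariates; ``mask``: [batch × T]
    ∈ {0,1}, one exactly where a TDM trough was drawn; ``y_reg``:
    [batch × T] troughs in μg/mL (NaN where masked out); ``y_cls``:
    [batch × T × 2] cumulative ordinal binaries (NaN where masked out);
    ``lengths``: true (unpadded) sequence lengths.
    """

    features: np.ndarray
    mask: np.ndarray
    y_reg: np.ndarray
    y_cls: np.ndarray
    lengths: np.ndarray
    course_ids: list[str] = field(default_factory=list)

    @property
    def n_observations(self) -> int:
        return int(self.mask.sum())

    def subset(self, idx: np.ndarray) -> "SequenceBatch":
        idx = np.asarray(idx)
        return SequenceBatch(
            self.features[idx],
            self.mask[idx],
            self.y_reg[idx],
            self.y_cls[idx],
            self.lengths[idx],
            [self.course_ids[i] for i in idx],
        )


def course_targets(course: PatientCourse) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dose (mask, y_reg, y_cls) arrays for one course.

    Each TDM draw is attached to the latest dose preceding it; if two draws
    attach to the same dose the later one wins.
    """
    n = len(course.dose_events)
    mask = np.zeros(n)
    y_reg = np.full(n, TARGET_SENTINEL)
    y_cls = np.full((n, 2), TARGET_SENTINEL)
    for m in course.tdm_measurements:
        preceding = None
        for j, d in enumerate(course.dose_events):
            if d.time < m.time:
                preceding = j
        if preceding is not None:
            mask[preceding] = 1.0
            y_reg[preceding] = m.trough_ug_ml
            y_cls[preceding] = encode_ordinal(m.trough_ug_ml)
    return mask, y_reg, y_cls


def assemble_batches(
    courses: list[PatientCourse],
    scaler: ScalerState,
    max_len: int = 25,
    training: bool = True,
    coeffs: PkCoefficients = PkCoefficients(),
) -> SequenceBatch:
    """Featurize, scale, truncate/pad and mask a list of courses.

    Training sequences longer than ``max_len`` keep their most recent
    ``max_len`` events; evaluation sequences are never truncated.  Padding
    (scaled-feature zeros) is appended after the true length with mask 0,
    so padded steps contribute nothing to loss or metrics.  Courses whose
    records still lack creatinine after forward filling are excluded.
    """
    if not courses:
        raise ValueError("empty course list")
    rows, masks, regs, clss, ids = [], [], [], [], []
    for course in courses:
        try:
            feats = build_feature_sequence(course, coeffs)
        except MissingCreatinineError:
            continue
        if feats.shape[0] == 0:
            continue
        mask, y_reg, y_cls = course_targets(course)
        if training and feats.shape[0] > max_len:
            feats = feats[-max_len:]
            mask, y_reg, y_cls = mask[-max_len:], y_reg[-max_len:], y_cls[-max_len:]
        rows.append(scaler.transform(feats))
        masks.append(mask)
        regs.append(y_reg)
        clss.append(y_cls)
        ids.append(course.patient_id)
    if not rows:
        raise ValueError("no usable courses after exclusions")
    lengths = np.array([r.shape[0] for r in rows])
    t_max = int(lengths.max())
    nf = rows[0].shape[1]
    features = np.zeros((len(rows), t_max, nf))
    mask = np.zeros((len(rows), t_max))
    y_reg = np.full((len(rows), t_max), TARGET_SENTINEL)
    y_cls = np.full((len(rows), t_max, 2), TARGET_SENTINEL)
    for i, r in enumerate(rows):
        n = r.shape[0]
        features[i, :n] = r
        mask[i, :n] = masks[i]
        y_reg[i, :n] = regs[i]
        y_cls[i, :n] = clss[i]
    return SequenceBatch(features, mask, y_reg, y_cls, lengths, ids)
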