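"""Reference desk-scale experiments on synthetic cohorts.

These functions bundle the standard study protocols the package ships
with: train-and-compare-against-naive-baselines on one cohort, and the
population-shift fine-tuning experiment.  They are used both by the test
suite and by the reproduction script, so the protocols (cohort sizes,
splits, architecture, epoch budgets) live in one place.

The naive baselines are the two predictors any sequence model must beat
to be worth deploying: the constant training-mean predictor, and the
carry-last-TDM predictor (predict each trough as the patient's previous
measured trough, falling back to the training mean for a course's first
measurement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, shifted_cohort, simulate_cohort
from .evaluation import evaluate_predictions
from .model import GointMLP, GointMLPConfig, predict_course
from .pk import PatientCourse, build_feature_sequence
from .preprocessing import ScalerState, SequenceBatch, assemble_batches, course_targets
from .training import TrainConfig, fine_tune, masked_rmse_batch, train

__all__ = [
    "REFERENCE_MODEL",
    "REFERENCE_TRAIN",
    "BaselineResult",
    "ShiftResult",
    "constant_mean_rmse",
    "carry_last_rmse",
    "run_baseline_experiment",
    "run_shift_experiment",
]

#: The tuned architecture: 3 GRU layers x 15 hidden units, 15 MLPs of
#: 5 hidden layers x 64 units, lambda = 0.29.
REFERENCE_MODEL = GointMLPConfig()

#: Desk-scale optimisation protocol: the reference batch/patience rules at
#: a reduced epoch budget so a full run finishes in minutes on one CPU.
REFERENCE_TRAIN = TrainConfig(
    max_epochs=350,
    batch_size=128,
    learning_rate=1e-3,
    warmup_epochs=100,
    early_stop_patience=60,
    grad_clip_norm=0.5,
    lam=0.29,
)


def constant_mean_rmse(train_batch: SequenceBatch, test_batch: SequenceBatch) -> float:
    """RMSE of predicting the training-set mean trough everywhere."""
    mean = float(np.mean(train_batch.y_reg[train_batch.mask > 0]))
    m = test_batch.mask > 0
    return float(np.sqrt(np.mean((test_batch.y_reg[m] - mean) ** 2)))


def carry_last_rmse(
    train_batch: SequenceBatch, test_courses: list[PatientCourse]
) -> float:
    """RMSE of carrying each patient's previous measured trough forward.

    The first measurement of every course, having no predecessor, falls
    back to the training-set mean trough.
    """
    mean = float(np.mean(train_batch.y_reg[train_batch.mask > 0]))
    errors = []
    for course in test_courses:
        prev = None
        for m in course.tdm_measurements:
            pred = prev if prev is not None else mean
            errors.append(pred - m.trough_ug_ml)
            prev = m.trough_ug_ml
    if not errors:
        raise ValueError("test courses carry no trough measurements")
    return float(np.sqrt(np.mean(np.asarray(errors) ** 2)))


@dataclass
class BaselineResult:
    model_rmse: float
    model_r2: float
    model_mae: float
    constant_mean_rmse: float
    carry_last_rmse: float
    agreement_rate: float
    n_test_observations: int
    model: GointMLP
    scaler: ScalerState


def _split_courses(courses, test_fraction, rng):
    idx = rng.permutation(len(courses))
    n_test = int(round(test_fraction * len(courses)))
    test_idx, train_idx = idx[:n_test], idx[n_test:]
    return [courses[i] for i in train_idx], [courses[i] for i in test_idx]


def run_baseline_experiment(
    n_patients: int = 500,
    seed: int = 0,
    test_fraction: float = 0.25,
    model_config: GointMLPConfig = REFERENCE_MODEL,
    train_config: TrainConfig = REFERENCE_TRAIN,
) -> BaselineResult:
    """Train on a seeded synthetic cohort and compare with naive baselines.

    The cohort is split at the patient level (default 25% held out, the
    reference internal-validation proportion); the scaler is fitted on the
    training split only.
    """
    courses, _ = simulate_cohort(CohortConfig(n_patients=n_patients, seed=seed))
    rng = np.random.default_rng(seed)
    train_courses, test_courses = _split_courses(courses, test_fraction, rng)
    feats = np.vstack([build_feature_sequence(c) for c in train_courses])
    scaler = ScalerState.fit(feats)
    tc = TrainConfig(**{**train_config.__dict__, "seed": seed})
    mc = GointMLPConfig(**{**model_config.__dict__, "seed": seed})
    train_batch = assemble_batches(train_courses, scaler)
    test_batch = assemble_batches(test_courses, scaler, training=False)
    model, _ = train(train_batch, tc, mc)

    y, _ = model.predict_arrays(test_batch.features)
    records, truths = [], []
    for course in test_courses:
        recs = predict_course(model, course, scaler)
        mask, y_reg, _ = course_targets(course)
        for t in np.flatnonzero(mask):
            records.append(recs[t])
            truths.append(float(y_reg[t]))
    report = evaluate_predictions(
        y, test_batch.y_reg, test_batch.mask, records=records, true_troughs=truths
    )
    return BaselineResult(
        model_rmse=report.rmse,
        model_r2=report.r2,
        model_mae=report.mae,
        constant_mean_rmse=constant_mean_rmse(train_batch, test_batch),
        carry_last_rmse=carry_last_rmse(train_batch, test_courses),
        agreement_rate=report.agreement_rate,
        n_test_observations=report.n,
        model=model,
        scaler=scaler,
    )


@dataclass
class ShiftResult:
    rmse_before: float
    rmse_after: float
    n_heldout_observations: int


def run_shift_experiment(
    seed: int = 0,
    n_base: int = 400,
    n_shifted: int = 300,
    finetune_fraction: float = 0.10,
    model_config: GointMLPConfig = REFERENCE_MODEL,
    train_config: TrainConfig = REFERENCE_TRAIN,
    finetune_epochs: int = 150,
    finetune_lr: float = 1e-4,
) -> ShiftResult:
    """Population-shift experiment: pretrain, evaluate, fine-tune, re-evaluate.

    A model trained on the base cohort is evaluated on a shifted cohort
    (younger, heavier, more aggressively dosed, and with a clearance
    miscalibration no covariate explains), then fine-tuned on 10% of the
    shifted patients (patient-level sample) and re-evaluated on the
    remaining 90%.  Fine-tuning runs at a reduced learning rate with
    early stopping on a validation split carved from the fine-tuning
    subset itself — the adaptation sees nothing of the held-out 90%.
    """
    base_courses, _ = simulate_cohort(CohortConfig(n_patients=n_base, seed=seed))
    shift_courses, _ = shifted_cohort(
        CohortConfig(n_patients=n_shifted, seed=seed + 1000)
    )
    feats = np.vstack([build_feature_sequence(c) for c in base_courses])
    scaler = ScalerState.fit(feats)
    tc = TrainConfig(**{**train_config.__dict__, "seed": seed})
    mc = GointMLPConfig(**{**model_config.__dict__, "seed": seed})
    base_batch = assemble_batches(base_courses, scaler)
    shifted_batch = assemble_batches(shift_courses, scaler, training=False)
    model, _ = train(base_batch, tc, mc)

    ft_config = TrainConfig(
        **{
            **tc.__dict__,
            "max_epochs": finetune_epochs,
            "learning_rate": finetune_lr,
            "warmup_epochs": 0,
            "early_stop_patience": 20,
        }
    )
    tuned = GointMLP(mc)
    tuned.set_params(model.clone_params())
    tuned, _, used = fine_tune(tuned, shifted_batch, finetune_fraction, ft_config)
    held = np.setdiff1d(np.arange(shifted_batch.features.shape[0]), used)
    heldout = shifted_batch.subset(held)
    return ShiftResult(
        rmse_before=masked_rmse_batch(model, heldout),
        rmse_after=masked_rmse_batch(tuned, heldout),
        n_heldout_observations=heldout.n_observations,
    )
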