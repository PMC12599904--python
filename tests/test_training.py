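"""Optimisation loop: early stopping, clipping, fine-tuning, search."""

import dataclasses

import numpy as np
import pytest

from deeptdm.cohort import CohortConfig, shifted_cohort, simulate_cohort
from deeptdm.model import GointMLP, GointMLPConfig
from deeptdm.pk import build_feature_sequence
from deeptdm.preprocessing import ScalerState, assemble_batches
from deeptdm.training import (
    Adam,
    TrainConfig,
    fine_tune,
    masked_rmse_batch,
    search_hyperparameters,
    train,
)

from conftest import SMALL_MODEL, SMALL_TRAIN


def constant_mean_rmse(train_batch, test_batch):
    m_tr = train_batch.mask > 0
    mean = float(np.mean(train_batch.y_reg[m_tr]))
    m_te = test_batch.mask > 0
    return float(np.sqrt(np.mean((test_batch.y_reg[m_te] - mean) ** 2)))


class TestTrain:
    def test_beats_constant_mean_on_synthetic_cohort(self, small_cohort, fitted_scaler):
        courses, _ = small_cohort
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(courses))
        tr = assemble_batches([courses[i] for i in idx[:90]], fitted_scaler)
        te = assemble_batches([courses[i] for i in idx[90:]], fitted_scaler,
                              training=False)
        model, history = train(tr, SMALL_TRAIN, SMALL_MODEL)
        assert masked_rmse_batch(model, te) < constant_mean_rmse(tr, te)
        assert history.best_epoch >= SMALL_TRAIN.warmup_epochs

    def test_no_observations_is_training_impossible(self, small_batch):
        empty = dataclasses.replace(
            small_batch.subset(np.arange(4)),
            mask=np.zeros_like(small_batch.mask[:4]),
        )
        with pytest.raises(ValueError, match="impossible"):
            train(empty, SMALL_TRAIN, SMALL_MODEL)

    def test_degenerate_patience_stops_at_first_non_improving_epoch(self, small_batch):
        cfg = dataclasses.replace(SMALL_TRAIN, max_epochs=60, warmup_epochs=0,
                                  early_stop_patience=0, learning_rate=0.5)
        _, history = train(small_batch.subset(np.arange(30)), cfg, SMALL_MODEL)
        # with a huge learning rate validation deteriorates quickly
        assert history.stop_reason.startswith("early stop")
        stop_epoch = len(history.val_rmse) - 1
        assert history.val_rmse[stop_epoch] >= min(history.val_rmse[:stop_epoch])

    def test_same_seed_reproduces_history_exactly(self, small_batch):
        cfg = dataclasses.replace(SMALL_TRAIN, max_epochs=10, warmup_epochs=0,
                                  early_stop_patience=10)
        sub = small_batch.subset(np.arange(40))
        _, h1 = train(sub, cfg, SMALL_MODEL)
        _, h2 = train(sub, cfg, SMALL_MODEL)
        assert h1.train_loss == h2.train_loss
        assert h1.val_rmse == h2.val_rmse
        assert h1.best_epoch == h2.best_epoch

    def test_gradient_clipping_bounds_update_norm(self, small_batch):
        from deeptdm import autodiff as ad
        from deeptdm.model import masked_multitask_loss

        model = GointMLP(SMALL_MODEL)
        opt = Adam(model.params, lr=1e-3, clip_norm=0.5)
        sub = small_batch.subset(np.arange(20))
        for _ in range(5):
            opt.zero_grad()
            y, logits = model.forward(sub.features)
            loss = masked_multitask_loss(y, logits, sub.y_reg, sub.y_cls,
                                         sub.mask, 0.29)
            ad.backward(loss)
            opt.step()
            assert opt.last_grad_norm <= 0.5 + 1e-12

    def test_loss_non_increasing_on_noiseless_toy(self):
        """Sanity monotonicity: tiny LR on a clean target drives loss down."""
        cfg_c = CohortConfig(n_patients=20, seed=5, noise_sd=0.0, cl_iiv_sd=0.0,
                             vd_iiv_sd=0.0, tdm_probability=1.0)
        courses, _ = simulate_cohort(cfg_c)
        feats = np.vstack([build_feature_sequence(c) for c in courses])
        scaler = ScalerState.fit(feats)
        batch = assemble_batches(courses, scaler)
        cfg = TrainConfig(max_epochs=40, batch_size=64, learning_rate=1e-3,
                          warmup_epochs=0, early_stop_patience=40, seed=0)
        _, history = train(batch, cfg, SMALL_MODEL)
        smoothed = np.convolve(history.train_loss, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert np.all(np.diff(smoothed) < 0.05 * smoothed[0] + 1e-9)


@pytest.fixture(scope="module")
def shift_setup():
    base_courses, _ = simulate_cohort(CohortConfig(n_patients=120, seed=21))
    shift_courses, _ = shifted_cohort(CohortConfig(n_patients=80, seed=22))
    feats = np.vstack([build_feature_sequence(c) for c in base_courses])
    scaler = ScalerState.fit(feats)
    base = assemble_batches(base_courses, scaler)
    shifted = assemble_batches(shift_courses, scaler, training=False)
    model, _ = train(base, SMALL_TRAIN, SMALL_MODEL)
    return model, scaler, shifted


class TestFineTune:
    def test_adaptation_improves_shifted_rmse(self, shift_setup):
        model, scaler, shifted = shift_setup
        start = GointMLP(SMALL_MODEL)
        start.set_params(model.clone_params())
        cfg = dataclasses.replace(SMALL_TRAIN, max_epochs=60, warmup_epochs=10,
                                  early_stop_patience=20)
        tuned, _, used = fine_tune(start, shifted, 0.10, cfg)
        held = np.setdiff1d(np.arange(shifted.features.shape[0]), used)
        before = masked_rmse_batch(model, shifted.subset(held))
        after = masked_rmse_batch(tuned, shifted.subset(held))
        assert after < before

    def test_zero_learning_rate_is_null_update(self, shift_setup):
        model, _, shifted = shift_setup
        frozen = GointMLP(SMALL_MODEL)
        frozen.set_params(model.clone_params())
        cfg = dataclasses.replace(SMALL_TRAIN, max_epochs=3, warmup_epochs=0,
                                  early_stop_patience=3, learning_rate=0.0)
        tuned, _, _ = fine_tune(frozen, shifted, 0.5, cfg)
        for k, v in model.clone_params().items():
            assert np.allclose(tuned.params[k].value, v)

    def test_invalid_fraction_rejected(self, shift_setup):
        model, _, shifted = shift_setup
        with pytest.raises(ValueError):
            fine_tune(model, shifted, 0.0, SMALL_TRAIN)
        with pytest.raises(ValueError):
            fine_tune(model, shifted, 1.5, SMALL_TRAIN)


class TestSearch:
    def _quick(self, n=30):
        courses, _ = simulate_cohort(CohortConfig(n_patients=n, seed=9))
        feats = np.vstack([build_feature_sequence(c) for c in courses])
        scaler = ScalerState.fit(feats)
        return assemble_batches(courses, scaler)

    def test_budget_one_returns_single_sample(self):
        batch = self._quick()
        cfg = TrainConfig(max_epochs=3, batch_size=64, learning_rate=1e-3,
                          warmup_epochs=0, early_stop_patience=3, seed=0)
        best, score = search_hyperparameters(
            {"learning_rate": ("log", 1e-4, 1e-3)}, batch, k=2, budget=1,
            base_train=cfg, base_model=SMALL_MODEL, seed=3)
        assert set(best) == {"learning_rate"}
        assert np.isfinite(score)

    def test_recovers_planted_lambda(self):
        """With corrupted class labels, λ = 0 must win over λ = 10."""
        batch = self._quick()
        rng = np.random.default_rng(0)
        bad_cls = np.where(np.isfinite(batch.y_cls),
                           rng.integers(0, 2, batch.y_cls.shape).astype(float),
                           batch.y_cls)
        batch = dataclasses.replace(batch, y_cls=bad_cls)
        cfg = TrainConfig(max_epochs=25, batch_size=64, learning_rate=5e-3,
                          warmup_epochs=0, early_stop_patience=25, seed=0)
        best, _ = search_hyperparameters(
            {"lam": ("choice", [0.0, 10.0])}, batch, k=2, budget=6,
            base_train=cfg, base_model=SMALL_MODEL, seed=1)
        assert best["lam"] == 0.0

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            search_hyperparameters({}, self._quick(10), k=2, budget=0)
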