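"""Network components: GRU recurrence, attention MLPs, decision heads, loss."""

import numpy as np
import pytest
from scipy.special import expit

from deeptdm import autodiff as ad
from deeptdm.autodiff import Tensor
from deeptdm.model import (
    GointMLP,
    GointMLPConfig,
    gru_layer_step,
    masked_multitask_loss,
    predict_course,
)
from deeptdm.preprocessing import assemble_batches

from conftest import SMALL_MODEL, make_course


def reference_stacked_gru(features, weights, n_layers, hidden):
    """Hand-unrolled stacked-GRU recurrence in plain numpy (oracle).

    Implements, step by step and layer by layer:
      z = expit([h_prev, x] Wz); r = expit([h_prev, x] Wr);
      cand = tanh([r*h_prev, x] W); h = (1 - z)*h_prev + z*cand.
    """
    b, t, _ = features.shape
    h = [np.zeros((b, hidden)) for _ in range(n_layers)]
    out = np.zeros((b, t, hidden))
    for step in range(t):
        x = features[:, step, :]
        for i in range(n_layers):
            wz, wr, w = weights[i]
            hx = np.concatenate([h[i], x], axis=-1)
            z = expit(hx @ wz)
            r = expit(hx @ wr)
            cand = np.tanh(np.concatenate([r * h[i], x], axis=-1) @ w)
            h[i] = (1 - z) * h[i] + z * cand
            x = h[i]
        out[:, step, :] = x
    return out


class TestGruStep:
    def test_zero_weights_zero_state_fixed_point(self):
        x = Tensor(np.zeros((1, 4)), requires_grad=False)
        h = Tensor(np.zeros((1, 3)), requires_grad=False)
        zeros = lambda shape: Tensor(np.zeros(shape), requires_grad=False)
        out = gru_layer_step(x, h, zeros((7, 3)), zeros((7, 3)), zeros((7, 3)))
        assert np.all(out.value == 0)

    def test_gates_bounded_for_random_weights(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            hx = rng.normal(scale=3, size=(1, 5))
            z = expit(hx @ rng.normal(size=(5, 2)))
            assert np.all((z > 0) & (z < 1))

    def test_matches_hand_unrolled_reference(self):
        model = GointMLP(GointMLPConfig(
            n_features=4, gru_layers=3, hidden=2, n_mlps=1, mlp_layers=2,
            mlp_units=4, seed=7))
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 3, 4))
        weights = [
            tuple(model.params[f"gru{i}.{n}"].value for n in ("wz", "wr", "w"))
            for i in range(3)
        ]
        expected = reference_stacked_gru(x, weights, 3, 2)
        got = model.sequential_forward(x).value
        assert np.allclose(got, expected, atol=1e-6)

    def test_printed_update_variant_requires_square_and_ignores_candidate(self):
        rng = np.random.default_rng(2)
        h = Tensor(rng.normal(size=(1, 3)), requires_grad=False)
        x = Tensor(rng.normal(size=(1, 3)), requires_grad=False)
        ws = [Tensor(rng.normal(size=(6, 3)), requires_grad=False) for _ in range(3)]
        out = gru_layer_step(x, h, *ws, printed_update=True)
        z = expit(np.concatenate([h.value, x.value], -1) @ ws[0].value)
        assert np.allclose(out.value, (1 - z) * x.value + z * h.value)
        x_bad = Tensor(np.zeros((1, 5)), requires_grad=False)
        with pytest.raises(ValueError):
            gru_layer_step(x_bad, h, *ws, printed_update=True)


class TestSequentialForward:
    def test_causality_under_input_perturbation(self):
        model = GointMLP(SMALL_MODEL)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 6, 16))
        base = model.sequential_forward(x).value
        x2 = x.copy()
        x2[0, 4, :] += 1.0
        pert = model.sequential_forward(x2).value
        assert np.allclose(pert[0, :4], base[0, :4])
        assert not np.allclose(pert[0, 4:], base[0, 4:])

    def test_single_layer_reduces_to_step_loop(self):
        cfg = GointMLPConfig(n_features=5, gru_layers=1, hidden=3, n_mlps=1,
                             mlp_layers=2, mlp_units=4, seed=4)
        model = GointMLP(cfg)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 4, 5))
        h = Tensor(np.zeros((2, 3)), requires_grad=False)
        outs = []
        for t in range(4):
            h = gru_layer_step(
                Tensor(x[:, t, :], requires_grad=False), h,
                model.params["gru0.wz"], model.params["gru0.wr"],
                model.params["gru0.w"])
            outs.append(h.value)
        assert np.allclose(model.sequential_forward(x).value,
                           np.stack(outs, axis=1), atol=1e-12)

    def test_batch_independence(self):
        model = GointMLP(SMALL_MODEL)
        rng = np.random.default_rng(5)
        seq = rng.normal(size=(1, 5, 16))
        dup = np.concatenate([seq, seq], axis=0)
        out = model.sequential_forward(dup).value
        assert np.allclose(out[0], out[1])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            GointMLP(SMALL_MODEL).sequential_forward(np.zeros((1, 0, 16)))


class TestJointModule:
    def test_attention_normalised_and_uniform_under_zero_prior(self):
        model = GointMLP(SMALL_MODEL)
        rng = np.random.default_rng(6)
        h = Tensor(rng.normal(size=(50, SMALL_MODEL.hidden)), requires_grad=False)
        g1 = ad.leaky_relu(h @ model.params["mlp0.w0"] + model.params["mlp0.b0"], 0.01)
        att = ad.sparsemax(g1 * model.params["mlp0.prior"])
        assert np.allclose(att.value.sum(axis=-1), 1.0)
        zero_prior = ad.sparsemax(g1 * Tensor(np.zeros(SMALL_MODEL.mlp_units),
                                              requires_grad=False))
        assert np.allclose(zero_prior.value, 1.0 / SMALL_MODEL.mlp_units)


class TestDecisionModule:
    def test_rank_consistency_on_random_inputs(self):
        """P(trough > 15) >= P(trough > 20) for any input, shared-weight head."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            model = GointMLP(GointMLPConfig(
                n_features=16, gru_layers=1, hidden=4, n_mlps=2, mlp_layers=2,
                mlp_units=8, seed=trial))
            # push biases apart in both directions to exercise the clamp
            model.params["dec.bc0"].value = rng.normal(size=(1,))
            model.params["dec.bc1"].value = rng.normal(size=(1,))
            g = Tensor(rng.normal(size=(500, 16)), requires_grad=False)
            _, logits = model.decision_forward(g)
            probs = expit(logits.value)
            assert np.all(probs[:, 0] >= probs[:, 1] - 1e-12)

    def test_zero_weights_give_bias_outputs(self):
        model = GointMLP(SMALL_MODEL)
        width = SMALL_MODEL.n_mlps * SMALL_MODEL.mlp_units
        model.params["dec.wr"].value = np.zeros((width, 1))
        model.params["dec.br"].value = np.array([2.5])
        model.params["dec.wc"].value = np.zeros((width, 1))
        model.params["dec.bc0"].value = np.array([0.3])
        model.params["dec.bc1"].value = np.array([-0.2])
        g = Tensor(np.random.default_rng(8).normal(size=(10, width)),
                   requires_grad=False)
        y, logits = model.decision_forward(g)
        assert np.allclose(y.value, 2.5)
        assert np.allclose(expit(logits.value[:, 0]), expit(0.3))
        assert np.allclose(expit(logits.value[:, 1]), expit(-0.2))

    def test_forward_deterministic(self):
        model = GointMLP(SMALL_MODEL)
        x = np.random.default_rng(9).normal(size=(2, 5, 16))
        y1, l1 = model.forward(x)
        y2, l2 = model.forward(x)
        assert np.array_equal(y1.value, y2.value)
        assert np.array_equal(l1.value, l2.value)


class TestMaskedLoss:
    def _leaves(self, b=1, t=3):
        rng = np.random.default_rng(10)
        return Tensor(rng.normal(size=(b, t))), Tensor(rng.normal(size=(b, t, 2)))

    def test_full_mask_gives_zero_loss(self):
        y, logits = self._leaves()
        loss = masked_multitask_loss(
            y, logits, np.full((1, 3), np.nan), np.full((1, 3, 2), np.nan),
            np.zeros((1, 3)), lam=0.29)
        assert loss.value == 0.0

    def test_single_step_regression_term(self):
        y = Tensor(np.array([[18.0]]))
        logits = Tensor(np.zeros((1, 1, 2)))
        loss = masked_multitask_loss(
            y, logits, np.array([[16.0]]), np.full((1, 1, 2), np.nan),
            np.ones((1, 1)), lam=0.0)
        assert loss.value == pytest.approx(4.0)

    def test_perfect_classification_term_vanishes(self):
        y = Tensor(np.array([[16.0]]))
        logits = Tensor(np.array([[[50.0, -50.0]]]))  # saturated, correct
        y_cls = np.array([[[1.0, 0.0]]])
        loss = masked_multitask_loss(
            y, logits, np.array([[16.0]]), y_cls, np.ones((1, 1)), lam=1.0)
        assert loss.value == pytest.approx(0.0, abs=1e-15)

    def test_masked_steps_have_zero_gradient(self):
        """Finite differences and backprop both vanish where M = 0."""
        y, logits = self._leaves(b=2, t=4)
        mask = np.array([[1, 0, 1, 0], [0, 0, 1, 0]], dtype=float)
        y_reg = np.where(mask > 0, 17.0, np.nan)
        y_cls = np.where(mask[..., None] > 0, np.array([1.0, 0.0]), np.nan)
        loss = masked_multitask_loss(y, logits, y_reg, y_cls, mask, lam=0.29)
        ad.backward(loss)
        assert np.all(y.grad[mask == 0] == 0)
        assert np.all(logits.grad[mask == 0] == 0)
        # finite-difference check at one masked-out entry
        base = loss.value
        y2 = y.value.copy()
        y2[0, 1] += 1e-3
        loss2 = masked_multitask_loss(Tensor(y2), Tensor(logits.value), y_reg,
                                      y_cls, mask, lam=0.29)
        assert loss2.value == pytest.approx(base, abs=1e-15)

    def test_negative_lambda_rejected(self):
        y, logits = self._leaves()
        with pytest.raises(ValueError):
            masked_multitask_loss(y, logits, np.zeros((1, 3)),
                                  np.zeros((1, 3, 2)), np.ones((1, 3)), lam=-1.0)


class TestPrediction:
    def test_one_record_per_dose_and_consensus(self, fitted_scaler):
        model = GointMLP(SMALL_MODEL)
        course = make_course(n_doses=4, tdm=[(2, 17.0)])
        records = predict_course(model, course, fitted_scaler)
        assert len(records) == 4
        for r in records:
            assert 0.0 <= r.ordinal_probs[0] <= 1.0
            assert r.ordinal_probs[0] >= r.ordinal_probs[1]
            assert r.consensus == (r.class_pred == r.regression_class)

    def test_consensus_examples(self):
        from deeptdm.model import PredictionRecord

        agree = PredictionRecord(17.0, (0.9, 0.1), "therapeutic", True)
        assert agree.regression_class == "therapeutic"
        disagree = PredictionRecord(19.5, (0.9, 0.8), "toxic", False)
        assert disagree.regression_class == "therapeutic"
        assert not disagree.consensus

    def test_scaler_mismatch_rejected(self, fitted_scaler):
        import dataclasses

        model = GointMLP(SMALL_MODEL)
        bad = dataclasses.replace(fitted_scaler)
        bad = type(fitted_scaler)(
            feature_names=["a", "b"], mins=fitted_scaler.mins,
            maxs=fitted_scaler.maxs, binary_idx=[])
        with pytest.raises(ValueError):
            predict_course(model, make_course(), bad)

    def test_end_to_end_loss_bit_identical_across_runs(self, small_batch):
        sub = small_batch.subset(np.arange(8))
        vals = []
        for _ in range(2):
            model = GointMLP(SMALL_MODEL)
            y, logits = model.forward(sub.features)
            loss = masked_multitask_loss(y, logits, sub.y_reg, sub.y_cls,
                                         sub.mask, lam=0.29)
            vals.append(float(loss.value))
        assert vals[0] == vals[1]
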