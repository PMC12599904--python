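"""The GointMLP trough-prediction network.

Three stacked components map a padded covariate sequence to per-dose
predictions:

* **sequential module** — a stack of GRU layers (update gate z, reset gate
  r, candidate state h̃; the gates are pure matrix products of
  [h_{t-1}, x_t] with no bias terms) producing a hidden state per dose
  event;
* **joint module** — N parallel shallow MLPs over the top GRU state at each
  step; each MLP's first layer is an attention layer (LeakyReLU affine map,
  elementwise product with a learnable prior vector, sparsemax), followed
  by LeakyReLU affine layers;
* **decision module** — the N MLP outputs are concatenated and fed to a
  scalar regression head (trough in μg/mL) and a CORAL-style ordinal head:
  a shared weight vector with one bias per threshold {15, 20} μg/mL,
  the second bias clamped to ``min(b₁, b₂)`` so
  P(trough > 15) ≥ P(trough > 20) for every input.

Training minimises a masked multi-task objective: masked mean-squared
regression error plus λ times the masked binary cross-entropies of the
K−1 = 2 ordinal classifiers; dose events without a measured trough
contribute exactly zero loss and zero gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .pk import FEATURE_NAMES, PatientCourse, PkCoefficients, build_feature_sequence
from .preprocessing import CLASS_NAMES, ORDINAL_THRESHOLDS, ScalerState, trough_class

__all__ = [
    "GointMLPConfig",
    "GointMLP",
    "PredictionRecord",
    "gru_layer_step",
    "masked_multitask_loss",
    "predict_course",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GointMLPConfig:
    """Architecture hyperparameters.

    Defaults are the tuned values: 3 GRU layers of 15 hidden units, 15
    parallel MLPs of 5 hidden layers with 64 units, balancing weight
    λ = 0.29.  ``shared_ordinal`` switches between the rank-consistent
    shared-weight ordinal head (default) and independent per-threshold
    classifiers.  ``printed_update`` selects the literal printed GRU state
    update h_t = (1−z)⊙x_t + z⊙h_{t−1} (which ignores the candidate state
    and needs input width == hidden width) for comparison experiments; the
    default is the standard update h_t = (1−z)⊙h_{t−1} + z⊙h̃_t.
    """

    n_features: int = 16
    gru_layers: int = 3
    hidden: int = 15
    n_mlps: int = 15
    mlp_layers: int = 5
    mlp_units: int = 64
    lam: float = 0.29
    leaky_slope: float = 0.01
    shared_ordinal: bool = True
    printed_update: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.gru_layers < 1 or self.n_mlps < 1 or self.mlp_layers < 2:
            raise ValueError("need gru_layers >= 1, n_mlps >= 1, mlp_layers >= 2")


@dataclass
class PredictionRecord:
    """Per-dose prediction: trough, ordinal probabilities, consensus."""

    y_reg: float
    ordinal_probs: tuple[float, float]
    class_pred: str
    consensus: bool

    @property
    def regression_class(self) -> str:
        return CLASS_NAMES[trough_class(max(self.y_reg, 0.0))]


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    a = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-a, a, size=shape)


def gru_layer_step(
    x: Tensor,
    h_prev: Tensor,
    wz: Tensor,
    wr: Tensor,
    w: Tensor,
    printed_update: bool = False,
) -> Tensor:
    """One GRU step: gates from [h_{t-1}, x], candidate from [r⊙h_{t-1}, x]."""
    hx = ad.concat([h_prev, x], axis=-1)
    z = ad.sigmoid(hx @ wz)
    r = ad.sigmoid(hx @ wr)
    cand = ad.tanh(ad.concat([r * h_prev, x], axis=-1) @ w)
    one = ad.tensor(1.0, requires_grad=False)
    if printed_update:
        if x.shape[-1] != h_prev.shape[-1]:
            raise ValueError(
                "printed GRU update needs input width equal to hidden width"
            )
        return (one - z) * x + z * h_prev
    return (one - z) * h_prev + z * cand


class GointMLP:
    """Network parameters plus forward/loss computation."""

    def __init__(self, config: GointMLPConfig = GointMLPConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        p: dict[str, Tensor] = {}
        in_w = c.n_features
        for i in range(c.gru_layers):
            fan = in_w + c.hidden
            for name in ("wz", "wr", "w"):
                p[f"gru{i}.{name}"] = Tensor(_uniform(rng, (fan, c.hidden), fan))
            in_w = c.hidden
        for i in range(c.n_mlps):
            p[f"mlp{i}.w0"] = Tensor(_uniform(rng, (c.hidden, c.mlp_units), c.hidden))
            p[f"mlp{i}.b0"] = Tensor(np.zeros(c.mlp_units))
            p[f"mlp{i}.prior"] = Tensor(np.ones(c.mlp_units))
            for l in range(1, c.mlp_layers):
                p[f"mlp{i}.w{l}"] = Tensor(
                    _uniform(rng, (c.mlp_units, c.mlp_units), c.mlp_units)
                )
                p[f"mlp{i}.b{l}"] = Tensor(np.zeros(c.mlp_units))
        width = c.n_mlps * c.mlp_units
        p["dec.wr"] = Tensor(_uniform(rng, (width, 1), width))
        p["dec.br"] = Tensor(np.zeros(1))
        if c.shared_ordinal:
            p["dec.wc"] = Tensor(_uniform(rng, (width, 1), width))
            p["dec.bc0"] = Tensor(np.zeros(1))
            p["dec.bc1"] = Tensor(np.zeros(1))
        else:
            p["dec.wc"] = Tensor(_uniform(rng, (width, 2), width))
            p["dec.bc"] = Tensor(np.zeros(2))
        self.params = p

    # ------------------------------------------------------------------ #

    def sequential_forward(self, features: np.ndarray) -> Tensor:
        """Run the stacked GRU over [B × T × F]; returns top states [B × T × H]."""
        if features.ndim != 3:
            raise ValueError("features must be [batch, time, features]")
        b, t, _ = features.shape
        if t == 0:
            raise ValueError("empty sequence (T = 0)")
        c = self.config
        h = [Tensor(np.zeros((b, c.hidden)), requires_grad=False) for _ in range(c.gru_layers)]
        tops = []
        for step in range(t):
            x: Tensor = Tensor(features[:, step, :], requires_grad=False)
            for i in range(c.gru_layers):
                h[i] = gru_layer_step(
                    x,
                    h[i],
                    self.params[f"gru{i}.wz"],
                    self.params[f"gru{i}.wr"],
                    self.params[f"gru{i}.w"],
                    printed_update=c.printed_update,
                )
                x = h[i]
            tops.append(x)
        return ad.stack(tops, axis=1)

    def joint_forward(self, flat_h: Tensor) -> Tensor:
        """N parallel attention-MLPs over flattened states [BT × H] → [BT × N·U]."""
        c = self.config
        outs = []
        for i in range(c.n_mlps):
            g1 = ad.leaky_relu(
                flat_h @ self.params[f"mlp{i}.w0"] + self.params[f"mlp{i}.b0"],
                c.leaky_slope,
            )
            x = ad.sparsemax(g1 * self.params[f"mlp{i}.prior"])
            for l in range(1, c.mlp_layers):
                x = ad.leaky_relu(
                    x @ self.params[f"mlp{i}.w{l}"] + self.params[f"mlp{i}.b{l}"],
                    c.leaky_slope,
                )
            outs.append(x)
        return ad.concat(outs, axis=-1)

    def decision_forward(self, g: Tensor) -> tuple[Tensor, Tensor]:
        """Regression scalar and K−1 ordinal logits per row of [BT × N·U]."""
        c = self.config
        y = g @ self.params["dec.wr"] + self.params["dec.br"]
        if c.shared_ordinal:
            s = g @ self.params["dec.wc"]
            b0, b1 = self.params["dec.bc0"], self.params["dec.bc1"]
            logits = ad.concat([s + b0, s + ad.minimum(b0, b1)], axis=-1)
        else:
            logits = g @ self.params["dec.wc"] + self.params["dec.bc"]
        return y, logits

    def forward(self, features: np.ndarray) -> tuple[Tensor, Tensor]:
        """Full pass: [B × T × F] → (troughs [B × T], ordinal logits [B × T × 2])."""
        b, t, _ = features.shape
        h = self.sequential_forward(features)
        flat = ad.reshape(h, (b * t, self.config.hidden))
        g = self.joint_forward(flat)
        y, logits = self.decision_forward(g)
        return ad.reshape(y, (b, t)), ad.reshape(logits, (b, t, 2))

    # ------------------------------------------------------------------ #

    def predict_arrays(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference: predicted troughs [B × T] and ordinal probabilities [B × T × 2]."""
        y, logits = self.forward(features)
        probs = 1.0 / (1.0 + np.exp(-logits.value))
        return y.value, probs

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for k, v in values.items():
            self.params[k].value = np.array(v, dtype=float)


def masked_multitask_loss(
    y_pred: Tensor,
    logits: Tensor,
    y_reg: np.ndarray,
    y_cls: np.ndarray,
    mask: np.ndarray,
    lam: float,
) -> Tensor:
    """Masked MSE + λ · masked ordinal cross-entropy (mean per observation).

    ``y_reg``/``y_cls`` may hold NaN at masked-out steps; those steps
    contribute exactly zero to the value and to every gradient.  An
    all-zero mask yields a zero loss.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    m = np.asarray(mask, dtype=float)
    count = m.sum()
    if count == 0:
        return ad.tensor(0.0, requires_grad=False)
    mt = Tensor(m, requires_grad=False)
    y_filled = np.where(np.isfinite(y_reg), y_reg, 0.0)
    diff = y_pred - Tensor(y_filled, requires_grad=False)
    reg = ad.tsum(diff * diff * mt) * ad.tensor(1.0 / count, requires_grad=False)
    if lam == 0:
        return reg
    bce = ad.bce_with_logits(logits, y_cls)
    mcls = Tensor(m[..., None], requires_grad=False)
    cls = ad.tsum(bce * mcls) * ad.tensor(1.0 / count, requires_grad=False)
    return reg + ad.tensor(lam, requires_grad=False) * cls


def _decode_rank(probs: np.ndarray) -> int:
    """Predicted rank with repair: count thresholds cleared cumulatively."""
    rank = 0
    for p in probs:
        if p > 0.5:
            rank += 1
        else:
            break
    return rank


def predict_course(
    model: GointMLP,
    course: PatientCourse,
    scaler: ScalerState,
    coeffs: PkCoefficients = PkCoefficients(),
) -> list[PredictionRecord]:
    """One PredictionRecord per dose event of an (unscaled) course.

    The classifier class is decoded from the ordinal probabilities at 0.5
    cutoffs with rank repair; consensus re-buckets the regression output
    through the {15, 20} μg/mL thresholds and compares the two classes.
    """
    feats = build_feature_sequence(course, coeffs)
    if list(scaler.feature_names) != list(FEATURE_NAMES):
        raise ValueError("scaler was fitted on a different variable set")
    scaled = scaler.transform(feats)[None, :, :]
    y, probs = model.predict_arrays(scaled)
    records = []
    for t in range(scaled.shape[1]):
        rank = _decode_rank(probs[0, t])
        cls = CLASS_NAMES[rank]
        reg_cls = CLASS_NAMES[trough_class(max(float(y[0, t]), 0.0), ORDINAL_THRESHOLDS)]
        records.append(
            PredictionRecord(
                y_reg=float(y[0, t]),
                ordinal_probs=(float(probs[0, t, 0]), float(probs[0, t, 1])),
                class_pred=cls,
                consensus=(cls == reg_cls),
            )
        )
    return records


def save_checkpoint(path: str | Path, model: GointMLP, scaler: ScalerState) -> None:
    """Single JSON archive: config, weights, scaler, seed."""
    payload = {
        "config": asdict(model.config),
        "params": {k: v.value.tolist() for k, v in model.params.items()},
        "scaler": json.loads(scaler.to_json()),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[GointMLP, ScalerState]:
    payload = json.loads(Path(path).read_text())
    model = GointMLP(GointMLPConfig(**payload["config"]))
    model.set_params({k: np.asarray(v) for k, v in payload["params"].items()})
    scaler = ScalerState.from_json(json.dumps(payload["scaler"]))
    return model, scaler
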