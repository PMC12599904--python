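"""Optimisation: masked Adam updates, early stopping with warm-up,
gradient clipping, fine-tuning on a shifted cohort, hyperparameter search.

Weights are updated only through the masked objective, so dose events
without a measured trough never move the parameters.  Early stopping
tracks masked validation RMSE: the warm-up is a minimum epoch count before
stopping can trigger, and the returned weights are those of the best
post-warm-up validation epoch.  Gradient clipping rescales the global
gradient norm to the configured maximum (0.5 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .model import GointMLP, GointMLPConfig, masked_multitask_loss
from .preprocessing import SequenceBatch

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "train",
    "fine_tune",
    "search_hyperparameters",
    "DEFAULT_SEARCH_SPACE",
    "masked_rmse_batch",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults mirror the reference protocol: 1000 epochs, batch size 512,
    learning rate 5e-4, early-stopping patience 50 after a 300-epoch
    warm-up, gradient clipping at global norm 0.5.  ``val_fraction`` is the
    per-course (patient-level) share held out for early stopping.
    """

    max_epochs: int = 1000
    batch_size: int = 512
    learning_rate: float = 5e-4
    early_stop_patience: int = 50
    warmup_epochs: int = 300
    grad_clip_norm: float | None = 0.5
    lam: float = 0.29
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.max_epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ValueError(
                "max_epochs and batch_size must be positive, learning_rate nonnegative"
            )
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""


class Adam:
    """Adam with default moments (β₁=0.9, β₂=0.999) and optional
    global-norm gradient clipping applied before each update."""

    def __init__(self, params, lr, clip_norm=None, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.clip_norm = clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.t = 0
        self.last_grad_norm = 0.0

    def step(self) -> None:
        grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.value))
                 for k, t in self.params.items()}
        norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        if self.clip_norm is not None and norm > self.clip_norm > 0:
            scale = self.clip_norm / norm
            grads = {k: g * scale for k, g in grads.items()}
            norm = self.clip_norm
        self.last_grad_norm = norm
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, t in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            t.value = t.value - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None


def masked_rmse_batch(model: GointMLP, batch: SequenceBatch) -> float:
    """Masked RMSE of the regression head over a batch (μg/mL)."""
    y, _ = model.predict_arrays(batch.features)
    m = batch.mask > 0
    if not m.any():
        raise ValueError("batch has no masked-in observations")
    resid = y[m] - batch.y_reg[m]
    return float(np.sqrt(np.mean(resid**2)))


def _split_train_val(batch: SequenceBatch, fraction: float, rng) -> tuple:
    n = batch.features.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    if n_val >= n:
        raise ValueError("validation fraction leaves no training sequences")
    val_idx, train_idx = order[:n_val], order[n_val:]
    tr, va = batch.subset(train_idx), batch.subset(val_idx)
    if tr.n_observations == 0 or va.n_observations == 0:
        # rotate until both sides hold at least one observed trough
        for shift in range(1, n):
            rolled = np.roll(order, shift)
            tr = batch.subset(rolled[n_val:])
            va = batch.subset(rolled[:n_val])
            if tr.n_observations > 0 and va.n_observations > 0:
                break
    return tr, va


def _run_epochs(
    model: GointMLP,
    train_batch: SequenceBatch,
    val_batch: SequenceBatch | None,
    config: TrainConfig,
    opt: Adam,
    rng: np.random.Generator,
) -> TrainHistory:
    history = TrainHistory()
    best = (np.inf, None)
    patience_left = config.early_stop_patience
    n = train_batch.features.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_mb = 0
        for start in range(0, n, config.batch_size):
            mb = train_batch.subset(order[start : start + config.batch_size])
            if mb.n_observations == 0:
                continue
            opt.zero_grad()
            y, logits = model.forward(mb.features)
            loss = masked_multitask_loss(
                y, logits, mb.y_reg, mb.y_cls, mb.mask, config.lam
            )
            ad.backward(loss)
            opt.step()
            epoch_loss += float(loss.value)
            n_mb += 1
        history.train_loss.append(epoch_loss / max(n_mb, 1))
        if val_batch is None:
            continue
        rmse = masked_rmse_batch(model, val_batch)
        history.val_rmse.append(rmse)
        if epoch >= config.warmup_epochs:
            if rmse < best[0]:
                best = (rmse, model.clone_params())
                history.best_epoch = epoch
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left < 0:
                    history.stop_reason = f"early stop at epoch {epoch}"
                    break
    else:
        history.stop_reason = "max_epochs reached"
    if val_batch is not None:
        if best[1] is None:
            # training never reached warm-up; keep final weights
            history.best_epoch = len(history.val_rmse) - 1
            history.stop_reason += " (warm-up not completed; final weights kept)"
        else:
            model.set_params(best[1])
    return history


def train(
    batch: SequenceBatch,
    config: TrainConfig = TrainConfig(),
    model_config: GointMLPConfig | None = None,
) -> tuple[GointMLP, TrainHistory]:
    """Train a fresh model; returns the best-validation-epoch weights.

    The validation split is drawn at the sequence (course) level with the
    config seed, so identical seed + config reproduce the history exactly.
    """
    if batch.n_observations == 0:
        raise ValueError("training impossible: no masked-in trough observations")
    mc = model_config or GointMLPConfig(seed=config.seed, lam=config.lam)
    model = GointMLP(mc)
    rng = np.random.default_rng(config.seed)
    tr, va = _split_train_val(batch, config.val_fraction, rng)
    opt = Adam(model.params, config.learning_rate, config.grad_clip_norm)
    history = _run_epochs(model, tr, va, config, opt, rng)
    return model, history


def fine_tune(
    model: GointMLP,
    shifted: SequenceBatch,
    fraction: float,
    config: TrainConfig,
) -> tuple[GointMLP, TrainHistory, np.ndarray]:
    """Continue optimisation on ``fraction`` of the shifted cohort.

    The fraction is sampled at the patient (sequence) level with the config
    seed.  Returns the adapted model, the fine-tuning history, and the
    indices of the sequences used, so callers can hold them out of the
    evaluation set.  ``fraction = 1`` is ordinary continued training.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = shifted.features.shape[0]
    n_take = int(round(fraction * n))
    if n_take == 0:
        raise ValueError("fraction selects zero patients")
    rng = np.random.default_rng(config.seed)
    take = rng.permutation(n)[:n_take]
    sub = shifted.subset(take)
    if sub.n_observations == 0:
        raise ValueError("selected fine-tuning patients carry no trough observations")
    if n_take > 1:
        tr, va = _split_train_val(sub, config.val_fraction, rng)
    else:
        tr = va = sub
    opt = Adam(model.params, config.learning_rate, config.grad_clip_norm)
    history = _run_epochs(model, tr, va, config, opt, rng)
    return model, history, take


#: Hyperparameter ranges of the reference search protocol.
DEFAULT_SEARCH_SPACE: dict = {
    "learning_rate": ("log", 1e-5, 1e-2),
    "max_len": ("int", 1, 50),
    "hidden": ("int", 10, 20),
    "gru_layers": ("int", 3, 6),
    "n_mlps": ("int", 10, 20),
    "mlp_layers": ("int", 5, 10),
    "mlp_units": ("int", 32, 128),
}


def _sample(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, spec in space.items():
        kind = spec[0]
        if kind == "log":
            out[key] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "int":
            out[key] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "choice":
            out[key] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown space kind {kind!r}")
    return out


def search_hyperparameters(
    space: dict,
    batch: SequenceBatch,
    k: int = 5,
    budget: int = 10,
    base_train: TrainConfig = TrainConfig(),
    base_model: GointMLPConfig = GointMLPConfig(),
    seed: int = 0,
) -> tuple[dict, float]:
    """Random search with k-fold cross-validation over sequences.

    Each sampled configuration is trained on k−1 folds and scored by masked
    validation RMSE on the held-out fold; the configuration with the lowest
    mean RMSE wins.  Random sampling is the reference sampler; a Bayesian
    sampler can be plugged in by pre-sampling the candidate list.
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    n = batch.features.shape[0]
    folds = np.array_split(rng.permutation(n), k)
    best: tuple[float, dict | None] = (np.inf, None)
    model_keys = {f.name for f in GointMLPConfig.__dataclass_fields__.values()}
    train_keys = {f.name for f in TrainConfig.__dataclass_fields__.values()}
    for _ in range(budget):
        cand = _sample(space, rng)
        mc = replace(base_model, **{k_: v for k_, v in cand.items() if k_ in model_keys})
        tc = replace(base_train, **{k_: v for k_, v in cand.items() if k_ in train_keys})
        scores = []
        for f in range(k):
            val_idx = folds[f]
            train_idx = np.concatenate([folds[j] for j in range(k) if j != f])
            tr, va = batch.subset(train_idx), batch.subset(val_idx)
            if tr.n_observations == 0 or va.n_observations == 0:
                continue
            model = GointMLP(mc)
            opt = Adam(model.params, tc.learning_rate, tc.grad_clip_norm)
            _run_epochs(model, tr, None, tc, opt, np.random.default_rng(tc.seed))
            scores.append(masked_rmse_batch(model, va))
        mean = float(np.mean(scores)) if scores else np.inf
        if mean < best[0]:
            best = (mean, cand)
    assert best[1] is not None
    return best[1], best[0]
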