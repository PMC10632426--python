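"""Training loop for the attention-MIL head.

Optimisation recipe: per-epoch resampling of each patient's bag to K tiles
(default 512), Adam with decoupled 1% weight decay, a one-cycle learning-rate
and momentum schedule over 32 epochs (warm-up for the first 8), and patient
batches of 64.  A quarter of the training patients are held out as an inner
tune set whose loss and AUROC are recorded each epoch to monitor overfitting;
no early stopping is applied by default and the final-epoch parameters are
returned.

The one-cycle schedule rises half-cosine from ``max_lr / 25`` to ``max_lr``
over the warm-up, then decays half-cosine to ``max_lr * 1e-6``; with the same
modulation the Adam momentum (beta1) rises from 0.85 to 0.95 and returns to
0.85.  The conventional one-cycle policy moves momentum in the opposite sense
(high -> low -> high); set ``momentum_inverted=True`` to restore that
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .evaluation import auroc
from .features import FeatureBag
from .model import (
    DECAYED,
    AttMILParams,
    init_params,
    loss_and_grads,
    predict_scores,
    update_running_stats,
)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the optimisation recipe (defaults as described in
    the module docstring)."""

    K: int = 512
    epochs: int = 32
    max_lr: float = 1e-4
    final_lr_factor: float = 1e-6
    warmup_epochs: int = 8
    start_lr_factor: float = 1.0 / 25.0
    weight_decay: float = 0.01
    momentum_low: float = 0.85
    momentum_high: float = 0.95
    momentum_inverted: bool = False
    batch_patients: int = 64
    beta2: float = 0.99
    adam_eps: float = 1e-8
    dropout: float = 0.5
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.warmup_epochs < self.epochs):
            raise ValueError("need 0 < warmup_epochs < epochs")
        if not (0.0 < self.start_lr_factor < 1.0):
            raise ValueError("start_lr_factor must be in (0, 1)")
        if not (self.momentum_low < self.momentum_high):
            raise ValueError("momentum_low must be < momentum_high")
        if self.K < 1 or self.batch_patients < 1:
            raise ValueError("K and batch_patients must be positive")


@dataclass
class TrainHistory:
    """Per-epoch training diagnostics."""

    train_loss: list[float] = field(default_factory=list)
    tune_loss: list[float] = field(default_factory=list)
    tune_auroc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    momentum: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "tune_loss": self.tune_loss,
                "tune_auroc": self.tune_auroc,
                "lr": self.lr,
                "momentum": self.momentum,
            }
        )


def _half_cosine(start: float, end: float, s: float) -> float:
    return start + (end - start) * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0))) / 2.0


def one_cycle(progress: float, cfg: TrainConfig) -> tuple[float, float]:
    """(learning rate, momentum) at training ``progress`` in [0, 1].

    Endpoints with the defaults: (max_lr/25, 0.85) at 0, (max_lr, 0.95) at the
    end of warm-up (progress = warmup_epochs/epochs), (max_lr * 1e-6, 0.85)
    at 1.
    """
    if not (0.0 <= progress <= 1.0):
        raise ValueError("progress must be in [0, 1]")
    pivot = cfg.warmup_epochs / cfg.epochs
    m_start, m_peak = cfg.momentum_low, cfg.momentum_high
    if cfg.momentum_inverted:
        m_start, m_peak = m_peak, m_start
    if progress <= pivot:
        s = progress / pivot
        lr = _half_cosine(cfg.max_lr * cfg.start_lr_factor, cfg.max_lr, s)
        mom = _half_cosine(m_start, m_peak, s)
    else:
        s = (progress - pivot) / (1.0 - pivot)
        lr = _half_cosine(cfg.max_lr, cfg.max_lr * cfg.final_lr_factor, s)
        mom = _half_cosine(m_peak, m_start, s)
    return float(lr), float(mom)


def resample_bag(bag: FeatureBag, K: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-size (K, d) resample of a bag's tiles.

    Bags with at least K tiles are subsampled without replacement; smaller
    bags are upsampled with replacement to exactly K rows.  A fresh draw is
    taken every epoch.
    """
    n = bag.n_tiles
    if n == 0:
        raise ValueError(f"empty bag for patient {bag.patient_id}")
    idx = rng.choice(n, size=K, replace=n < K)
    return bag.features[idx]


def _tune_metrics(
    tune_bags: Sequence[FeatureBag], labels: np.ndarray, params: AttMILParams
) -> tuple[float, float]:
    scores = predict_scores([b.features for b in tune_bags], params)
    eps = 1e-12
    p_true = np.where(labels == 1, scores, 1.0 - scores)
    loss = float(-np.log(np.clip(p_true, eps, None)).mean())
    try:
        a = auroc(scores, labels)
    except ValueError:
        a = float("nan")
    return loss, a


def train_model(
    train_bags: Sequence[FeatureBag],
    tune_bags: Sequence[FeatureBag],
    cfg: TrainConfig,
    target: str = "ER",
) -> tuple[AttMILParams, TrainHistory]:
    """Train the MIL head on ``train_bags``, monitoring ``tune_bags``.

    Fully reproducible from ``cfg.seed``: weight initialisation, per-epoch
    bag resampling, batch order and dropout masks all derive from it.
    Raises before training if the training labels contain a single class.
    """
    y_train = np.array([b.labels[target] for b in train_bags], dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            f"cannot train on single-class labels for target {target!r} "
            f"(counts: {np.bincount(y_train, minlength=2).tolist()})"
        )
    y_tune = np.array([b.labels[target] for b in tune_bags], dtype=int)
    d = train_bags[0].dim

    ss = np.random.SeedSequence(cfg.seed)
    init_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(1)[0])
    params = init_params(d, seed=init_seed, dropout=cfg.dropout,
                         extractor_name="unknown")

    class_weights = None
    if cfg.class_weighting:
        counts = np.bincount(y_train, minlength=2).astype(float)
        class_weights = counts.sum() / (2.0 * np.maximum(counts, 1.0))

    n = len(train_bags)
    n_batches = int(np.ceil(n / cfg.batch_patients))
    total_updates = cfg.epochs * n_batches
    m = {k: np.zeros_like(v) for k, v in params.weights().items()}
    v = {k: np.zeros_like(val) for k, val in params.weights().items()}
    history = TrainHistory()
    updates_done = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        lr = mom = None
        for b in range(n_batches):
            batch_idx = order[b * cfg.batch_patients : (b + 1) * cfg.batch_patients]
            bags = [resample_bag(train_bags[i], cfg.K, rng) for i in batch_idx]
            labels = y_train[batch_idx]
            lr, mom = one_cycle(updates_done / total_updates, cfg)
            loss, grads, bn_batch = loss_and_grads(
                bags, labels, params, rng, class_weights=class_weights
            )
            update_running_stats(params, bn_batch)
            t = updates_done + 1
            for k, g in grads.items():
                p = getattr(params, k)
                if cfg.weight_decay > 0 and k in DECAYED:
                    p -= lr * cfg.weight_decay * p  # decoupled decay
                m[k] = mom * m[k] + (1.0 - mom) * g
                v[k] = cfg.beta2 * v[k] + (1.0 - cfg.beta2) * g * g
                m_hat = m[k] / (1.0 - mom**t)
                v_hat = v[k] / (1.0 - cfg.beta2**t)
                p -= lr * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)
            updates_done += 1
            epoch_losses.append(loss)
        tune_loss, tune_auc = (
            _tune_metrics(tune_bags, y_tune, params) if len(tune_bags) else (np.nan, np.nan)
        )
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.tune_loss.append(tune_loss)
        history.tune_auroc.append(tune_auc)
        history.lr.append(lr)
        history.momentum.append(mom)
    return params, history


def config_dict(cfg: TrainConfig) -> dict:
    return asdict(cfg)
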