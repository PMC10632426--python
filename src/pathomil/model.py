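"""Attention-based multiple-instance-learning head.

Architecture, for a bag of K tile feature vectors x_k in R^d:

* embedding: fully connected d -> 256 with ReLU, then a linear 256 -> 256
  layer producing the tile embedding h_k;
* attention: a_k = softmax_k( w^T tanh(V h_k) ) with V in R^{128x256},
  w in R^{128} -- a learned, permutation-invariant weighting of tiles;
* pooling: h_sum = sum_k a_k h_k, one 256-vector per bag;
* classifier: BatchNorm1d over the batch of h_sum vectors, dropout p = 0.5,
  a fully connected 256 -> 2 layer, and a softmax giving the slide-level
  class probabilities.

Only the bag label supervises training (weak supervision); the attention
vector is the model's own account of which tiles drove the prediction and is
reused for heatmaps and top-tile export.

Implemented directly in NumPy (float64) with an explicit backward pass; the
network is small enough that this is fast, exactly reproducible, and easy to
verify against scalar oracles and finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EMBED_DIM = 256
ATTN_DIM = 128
N_CLASSES = 2
BN_EPS = 1e-5
BN_MOMENTUM = 0.1

_WEIGHT_KEYS = ("W_embed", "b_embed", "W_proj", "b_proj", "V", "w", "bn_gamma",
                "bn_beta", "W_cls", "b_cls")
# parameters receiving decoupled weight decay (weight matrices only)
DECAYED = ("W_embed", "W_proj", "V", "w", "W_cls")


@dataclass
class AttMILParams:
    """All learnable weights plus batch-norm running statistics."""

    W_embed: np.ndarray  # (256, d)
    b_embed: np.ndarray  # (256,)
    W_proj: np.ndarray   # (256, 256)
    b_proj: np.ndarray   # (256,)
    V: np.ndarray        # (128, 256)
    w: np.ndarray        # (128,)
    bn_gamma: np.ndarray  # (256,)
    bn_beta: np.ndarray   # (256,)
    W_cls: np.ndarray    # (2, 256)
    b_cls: np.ndarray    # (2,)
    bn_mean: np.ndarray = field(default_factory=lambda: np.zeros(EMBED_DIM))
    bn_var: np.ndarray = field(default_factory=lambda: np.ones(EMBED_DIM))
    dropout: float = 0.5
    extractor_name: str = "unknown"

    @property
    def input_dim(self) -> int:
        return self.W_embed.shape[1]

    def weights(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in _WEIGHT_KEYS}

    def copy(self) -> "AttMILParams":
        return AttMILParams(
            **{k: getattr(self, k).copy() for k in _WEIGHT_KEYS},
            bn_mean=self.bn_mean.copy(),
            bn_var=self.bn_var.copy(),
            dropout=self.dropout,
            extractor_name=self.extractor_name,
        )


@dataclass
class BagPrediction:
    probs: np.ndarray      # (2,) class probabilities, sum to 1
    score: float           # probability of the positive class (index 1)
    attention: np.ndarray  # (K,) attention weights, sum to 1


def init_params(d: int, seed: int = 0, dropout: float = 0.5,
                extractor_name: str = "unknown") -> AttMILParams:
    """Seeded uniform fan-in initialisation U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)

    def unif(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return AttMILParams(
        W_embed=unif((EMBED_DIM, d), d),
        b_embed=unif((EMBED_DIM,), d),
        W_proj=unif((EMBED_DIM, EMBED_DIM), EMBED_DIM),
        b_proj=unif((EMBED_DIM,), EMBED_DIM),
        V=unif((ATTN_DIM, EMBED_DIM), EMBED_DIM),
        w=unif((ATTN_DIM,), ATTN_DIM),
        bn_gamma=np.ones(EMBED_DIM),
        bn_beta=np.zeros(EMBED_DIM),
        W_cls=unif((N_CLASSES, EMBED_DIM), EMBED_DIM),
        b_cls=unif((N_CLASSES,), EMBED_DIM),
        dropout=dropout,
        extractor_name=extractor_name,
    )


# ---------------------------------------------------------------------------
# forward pieces


def embed(features: np.ndarray, params: AttMILParams) -> np.ndarray:
    """Tile embeddings ``h_k = W_proj @ relu(W_embed @ x_k + b1) + b2``; (K, 256)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be (K, d)")
    if X.shape[1] != params.input_dim:
        raise ValueError(
            f"feature dimension mismatch: expected {params.input_dim}, got {X.shape[1]}"
        )
    A1 = np.maximum(X @ params.W_embed.T + params.b_embed, 0.0)
    return A1 @ params.W_proj.T + params.b_proj


def attention_logits(h: np.ndarray, params: AttMILParams) -> np.ndarray:
    """Unnormalised attention ``e_k = w^T tanh(V h_k)``; (K,)."""
    return np.tanh(h @ params.V.T) @ params.w


def attention_scores(h: np.ndarray, params: AttMILParams) -> np.ndarray:
    """Softmax attention over tiles: ``a_k = exp(e_k) / sum_j exp(e_j)``.

    Stabilised by max-subtraction; entries are positive and sum to 1.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ValueError("empty bag: attention is undefined")
    e = attention_logits(h, params)
    e = e - e.max()
    a = np.exp(e)
    return a / a.sum()


def mil_pool(h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention pooling ``h_sum = sum_i a_i h_i``; (256,)."""
    h, a = np.asarray(h, float), np.asarray(a, float)
    if h.shape[0] != a.shape[0]:
        raise ValueError(f"length mismatch: {h.shape[0]} embeddings vs {a.shape[0]} weights")
    return a @ h


def classify(
    h_sum: np.ndarray,
    params: AttMILParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Classifier head on a batch of pooled representations; (B, 2) probabilities.

    Evaluation mode uses batch-norm running statistics and identity dropout,
    hence is deterministic; training mode uses batch statistics and seeded
    dropout (``rng`` required).
    """
    S = np.atleast_2d(np.asarray(h_sum, dtype=float))
    if training:
        mu = S.mean(axis=0)
        var = S.var(axis=0)
    else:
        mu, var = params.bn_mean, params.bn_var
    Y = params.bn_gamma * (S - mu) / np.sqrt(var + BN_EPS) + params.bn_beta
    if training and params.dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        mask = rng.random(Y.shape) >= params.dropout
        Y = Y * mask / (1.0 - params.dropout)
    logits = Y @ params.W_cls.T + params.b_cls
    logits = logits - logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    return P / P.sum(axis=1, keepdims=True)


def forward(
    features: np.ndarray,
    params: AttMILParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> BagPrediction:
    """Full bag forward pass: embed, attend, pool, classify.

    Evaluation-mode predictions are permutation-invariant over tiles and
    deterministic.
    """
    h = embed(features, params)
    a = attention_scores(h, params)
    h_sum = mil_pool(h, a)
    probs = classify(h_sum, params, training=training, rng=rng)[0]
    return BagPrediction(probs=probs, score=float(probs[1]), attention=a)


def predict_scores(
    bags_features: list[np.ndarray], params: AttMILParams
) -> np.ndarray:
    """Evaluation-mode positive-class score for each bag."""
    return np.array([forward(X, params).score for X in bags_features])


# ---------------------------------------------------------------------------
# training-mode loss and gradients (explicit backward pass)


def loss_and_grads(
    bags: list[np.ndarray],
    labels: np.ndarray,
    params: AttMILParams,
    rng: np.random.Generator,
    class_weights: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Mean cross-entropy over a batch of bags and its gradients.

    Returns ``(loss, grads, bn_batch)`` where ``grads`` maps weight names to
    arrays of matching shape and ``bn_batch`` carries the batch mean/unbiased
    variance used to update the running statistics.
    """
    B = len(bags)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (B,):
        raise ValueError("labels must align with bags")
    caches = []
    S = np.empty((B, EMBED_DIM))
    for i, X in enumerate(bags):
        X = np.asarray(X, dtype=float)
        Z1 = X @ params.W_embed.T + params.b_embed
        A1 = np.maximum(Z1, 0.0)
        H = A1 @ params.W_proj.T + params.b_proj
        T = np.tanh(H @ params.V.T)
        e = T @ params.w
        e = e - e.max()
        a = np.exp(e)
        a = a / a.sum()
        S[i] = a @ H
        caches.append((X, Z1, A1, H, T, a))

    # batch norm (training statistics)
    mu = S.mean(axis=0)
    var = S.var(axis=0)
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    S_hat = (S - mu) * inv_std
    Y = params.bn_gamma * S_hat + params.bn_beta

    # dropout
    if params.dropout > 0:
        mask = (rng.random(Y.shape) >= params.dropout) / (1.0 - params.dropout)
    else:
        mask = np.ones_like(Y)
    D = Y * mask

    logits = D @ params.W_cls.T + params.b_cls
    logits = logits - logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P = P / P.sum(axis=1, keepdims=True)

    if class_weights is None:
        sample_w = np.ones(B)
    else:
        sample_w = np.asarray(class_weights, float)[labels]
    wsum = sample_w.sum()
    loss = float(-(sample_w * np.log(P[np.arange(B), labels] + 1e-300)).sum() / wsum)

    # ---- backward
    dlogits = P.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= (sample_w / wsum)[:, None]

    grads = {k: np.zeros_like(v) for k, v in params.weights().items()}
    grads["W_cls"] = dlogits.T @ D
    grads["b_cls"] = dlogits.sum(axis=0)
    dD = dlogits @ params.W_cls
    dY = dD * mask
    grads["bn_gamma"] = (dY * S_hat).sum(axis=0)
    grads["bn_beta"] = dY.sum(axis=0)
    dS_hat = dY * params.bn_gamma
    dS = (inv_std / B) * (
        B * dS_hat - dS_hat.sum(axis=0) - S_hat * (dS_hat * S_hat).sum(axis=0)
    )

    for i, (X, Z1, A1, H, T, a) in enumerate(caches):
        G = dS[i]
        dH = np.outer(a, G)
        da = H @ G
        de = a * (da - a @ da)
        grads["w"] += T.T @ de
        dM = de[:, None] * params.w[None, :] * (1.0 - T**2)
        grads["V"] += dM.T @ H
        dH += dM @ params.V
        grads["W_proj"] += dH.T @ A1
        grads["b_proj"] += dH.sum(axis=0)
        dA1 = dH @ params.W_proj
        dZ1 = dA1 * (Z1 > 0)
        grads["W_embed"] += dZ1.T @ X
        grads["b_embed"] += dZ1.sum(axis=0)

    n = max(B - 1, 1)
    bn_batch = {"mean": mu, "var": var * B / n}  # unbiased var for running stats
    return loss, grads, bn_batch


def update_running_stats(params: AttMILParams, bn_batch: dict[str, np.ndarray]) -> None:
    params.bn_mean = (1 - BN_MOMENTUM) * params.bn_mean + BN_MOMENTUM * bn_batch["mean"]
    params.bn_var = (1 - BN_MOMENTUM) * params.bn_var + BN_MOMENTUM * bn_batch["var"]


# ---------------------------------------------------------------------------
# checkpoint I/O (versioned npz + json sidecar metadata)

CHECKPOINT_VERSION = 1


def save_checkpoint(params: AttMILParams, path: str | Path,
                    train_config: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **params.weights(), bn_mean=params.bn_mean, bn_var=params.bn_var)
    meta = {
        "version": CHECKPOINT_VERSION,
        "input_dim": params.input_dim,
        "dropout": params.dropout,
        "extractor": params.extractor_name,
        "train_config": train_config or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path) -> AttMILParams:
    path = Path(path)
    data = np.load(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return AttMILParams(
        **{k: data[k] for k in _WEIGHT_KEYS},
        bn_mean=data["bn_mean"],
        bn_var=data["bn_var"],
        dropout=float(meta.get("dropout", 0.5)),
        extractor_name=str(meta.get("extractor", "unknown")),
    )
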