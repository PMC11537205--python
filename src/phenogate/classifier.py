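"""Compact trainable multiclass patch classifier.

A small fully-connected network over the flattened 41x41x3 patch with an
explicit per-sample normalization contract: the input is standardized per
sample and the hidden layer uses layer normalization, so every internal
feature normalization is computed from that sample alone and inference is
independent of batch composition and size (prediction runs sample by sample,
making batch invariance exact, not merely approximate).

Training follows the standard recipe for this task: class-balanced batches,
Adam, cross-entropy loss, a one-cycle learning-rate schedule, and checkpoint
selection by the lowest validation loss.  The backbone is deliberately
compact — the contract under test is the training/evaluation procedure, not a
particular deep architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .image import DimensionError
from .patches import PatchRecord, balanced_batch_indices
from .rules import CLASS_NAMES


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``n_steps`` defaults to the desk-scale 2,000; the full-scale value of
    20,000 steps remains selectable.  ``batch_size`` 256, Adam at learning
    rate 0.001 with a one-cycle schedule, cross-entropy loss, and selection of
    the checkpoint with the lowest validation loss.
    """

    n_steps: int = 2_000
    batch_size: int = 256
    learning_rate: float = 1e-3
    schedule: str = "one-cycle"
    n_classes: int = 14
    hidden_units: int = 64
    seed: int = 0
    checkpoint_every: int = 100
    warmup_fraction: float = 0.3
    final_lr_fraction: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("n_steps", "batch_size", "n_classes", "hidden_units", "checkpoint_every"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.schedule not in ("one-cycle", "constant"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")


def one_cycle_lr(step: int, config: TrainConfig) -> float:
    """One-cycle schedule: linear warmup to the peak rate, cosine anneal down."""
    if config.schedule == "constant":
        return config.learning_rate
    peak = config.learning_rate
    warm = max(1, int(config.warmup_fraction * config.n_steps))
    if step < warm:
        start = peak / 25.0
        return start + (peak - start) * step / warm
    frac = (step - warm) / max(1, config.n_steps - warm)
    floor = peak * config.final_lr_fraction
    return floor + 0.5 * (peak - floor) * (1 + np.cos(np.pi * frac))


class PatchClassifier:
    """Two-layer network with per-sample input standardization and layer norm."""

    def __init__(self, input_dim: int, class_names: Sequence[str], hidden_units: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_dim = int(input_dim)
        self.class_names = list(class_names)
        h, d, k = hidden_units, input_dim, len(self.class_names)
        # He initialization
        self.params = {
            "W1": (rng.standard_normal((d, h)) * np.sqrt(2.0 / d)).astype(np.float64),
            "b1": np.zeros(h),
            "gamma": np.ones(h),
            "beta": np.zeros(h),
            "W2": (rng.standard_normal((h, k)) * np.sqrt(2.0 / h)).astype(np.float64),
            "b2": np.zeros(k),
        }

    # -- forward -------------------------------------------------------------

    @staticmethod
    def _standardize(X: np.ndarray) -> np.ndarray:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        return (X - mu) / (sd + 1e-8)

    def _forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        Xs = self._standardize(X)
        Z1 = Xs @ p["W1"] + p["b1"]
        mu = Z1.mean(axis=1, keepdims=True)
        var = Z1.var(axis=1, keepdims=True)
        Z1n = (Z1 - mu) / np.sqrt(var + 1e-8)
        H1 = p["gamma"] * Z1n + p["beta"]
        A1 = np.maximum(H1, 0.0)
        scores = A1 @ p["W2"] + p["b2"]
        if cache:
            return scores, (Xs, Z1, Z1n, mu, var, A1)
        return scores

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores (logits), computed sample by sample.

        Processing each sample independently makes inference exactly invariant
        to batch composition and size.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != self.input_dim:
            raise DimensionError(f"expected {self.input_dim} features, got {X.shape[1]}")
        out = np.empty((X.shape[0], len(self.class_names)))
        for i in range(X.shape[0]):
            out[i] = self._forward(X[i : i + 1])[0]
        return out

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (labels, scores); the label is always the max-score class."""
        s = self.scores(X)
        idx = s.argmax(axis=1)
        labels = np.array([self.class_names[i] for i in idx], dtype=object)
        return labels, s

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (.npz) with a JSON sidecar recording the class list."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "class_names": self.class_names,
                    "input_dim": self.input_dim,
                    "hidden_units": int(self.params["W1"].shape[1]),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["input_dim"], meta["class_names"], meta["hidden_units"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            model.params = {k: z[k] for k in z.files}
        return model


def _stack(patches: Sequence[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.pixels.reshape(-1) for p in patches]).astype(np.float64)
    y = np.array([p.label for p in patches], dtype=object)
    return X, y


def _cross_entropy(scores: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    shifted = scores - scores.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logsumexp
    n = scores.shape[0]
    loss = -logp[np.arange(n), y_idx].mean()
    grad = np.exp(logp)
    grad[np.arange(n), y_idx] -= 1.0
    return float(loss), grad / n


def evaluate_loss(model: PatchClassifier, patches: Sequence[PatchRecord]) -> float:
    """Mean cross-entropy of a patch set under the (per-sample) inference path."""
    X, y = _stack(patches)
    index = {c: i for i, c in enumerate(model.class_names)}
    y_idx = np.array([index[v] for v in y])
    scores = model.scores(X)
    loss, _ = _cross_entropy(scores, y_idx)
    return loss


def train_classifier(
    train_patches: Sequence[PatchRecord],
    val_patches: Sequence[PatchRecord],
    config: TrainConfig,
    class_names: Sequence[str] | None = None,
) -> tuple[PatchClassifier, pd.DataFrame]:
    """Train a patch classifier under the balanced-batch / one-cycle contract.

    Returns the model restored to the checkpoint with the lowest validation
    loss, plus a training log (step, lr, train_loss, val_loss, best_val_loss).
    Deterministic given ``config.seed`` up to floating-point reduction order.
    """
    if not train_patches or not val_patches:
        raise ConfigurationError("both training and validation splits must be non-empty")
    if class_names is None:
        class_names = list(CLASS_NAMES)[: config.n_classes]
    X_train, y_train = _stack(train_patches)
    index = {c: i for i, c in enumerate(class_names)}
    y_idx = np.array([index[v] for v in y_train])

    model = PatchClassifier(X_train.shape[1], class_names, config.hidden_units, seed=config.seed)
    p = model.params
    adam_m = {k: np.zeros_like(v) for k, v in p.items()}
    adam_v = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    batches = balanced_batch_indices(
        y_train, batch_size=config.batch_size, class_names=class_names, seed=config.seed
    )

    best_val = np.inf
    best_params = {k: v.copy() for k, v in p.items()}
    log_rows: list[dict] = []

    for step in range(config.n_steps):
        lr = one_cycle_lr(step, config)
        idx = next(batches)
        Xb, yb = X_train[idx], y_idx[idx]
        scores, (Xs, Z1, Z1n, mu, var, A1) = model._forward(Xb, cache=True)
        loss, dscores = _cross_entropy(scores, yb)

        # backward
        grads = {}
        grads["W2"] = A1.T @ dscores
        grads["b2"] = dscores.sum(axis=0)
        dA1 = dscores @ p["W2"].T
        dH1 = dA1 * (A1 > 0)
        grads["gamma"] = (dH1 * Z1n).sum(axis=0)
        grads["beta"] = dH1.sum(axis=0)
        dZ1n = dH1 * p["gamma"]
        inv_std = 1.0 / np.sqrt(var + 1e-8)
        dZ1 = (
            dZ1n - dZ1n.mean(axis=1, keepdims=True) - Z1n * (dZ1n * Z1n).mean(axis=1, keepdims=True)
        ) * inv_std
        grads["W1"] = Xs.T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)

        t = step + 1
        for k in p:
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
            m_hat = adam_m[k] / (1 - beta1**t)
            v_hat = adam_v[k] / (1 - beta2**t)
            p[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

        if (step + 1) % config.checkpoint_every == 0 or step + 1 == config.n_steps:
            val_loss = evaluate_loss(model, val_patches)
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in p.items()}
            log_rows.append(
                {
                    "step": step + 1,
                    "lr": lr,
                    "train_loss": loss,
                    "val_loss": val_loss,
                    "best_val_loss": best_val,
                }
            )

    model.params = best_params
    log = pd.DataFrame(log_rows)
    return model, log


def predict_patches(
    model: PatchClassifier, patches: Sequence[PatchRecord]
) -> pd.DataFrame:
    """Predict labels and per-class scores for a list of patches."""
    X, _ = _stack(patches)
    labels, scores = model.predict(X)
    out = pd.DataFrame(
        {
            "instance_id": [p.instance_id for p in patches],
            "true_class": [p.label for p in patches],
            "pred_class": labels,
        }
    )
    for j, c in enumerate(model.class_names):
        out[f"score_{c}"] = scores[:, j]
    return out
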