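"""Shared training loop for the three window classifiers.

Plain SGD (momentum optional, zero by default), batch size 64, up to 100
epochs. Class balance is restored by random under-sampling of the majority
classes once per run, before training. Epoch-level validation weighted F1
drives both the learning-rate schedule (×0.2 after 20 stagnant epochs) and
early stopping (patience 40); the best-epoch weights are restored at the
end. All randomness (under-sampling, shuffling, dropout) flows from the
config seed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..evaluation import counts_from_predictions, f1_weighted
from ..svm import undersample
from .layers import softmax_xent
from .models import CLASSES, ModelSpec

__all__ = ["TrainConfig", "train_model", "predict_proba"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 40
    lr_patience: int = 20
    lr_factor: float = 0.2
    momentum: float = 0.0
    seed: int = 0
    undersample: bool = True
    min_delta: float = 1e-4
    stop_at_f1: float | None = None  # optional early exit once reached

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.early_stop_patience,
               self.lr_patience) <= 0 or self.lr_factor <= 0:
            raise ValueError("all training-schedule values must be positive")
        if self.early_stop_patience <= self.lr_patience:
            raise ValueError("early-stop patience must exceed the LR patience")


def _encode(labels) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([lookup[str(c)] for c in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from None


def _val_f1(spec: ModelSpec, x_val, y_val_labels) -> float:
    preds = []
    for i in range(0, len(x_val), 256):
        preds.extend(spec.predict_classes(x_val[i : i + 256]))
    return f1_weighted(counts_from_predictions(y_val_labels, preds))


def train_model(
    spec: ModelSpec,
    x_train: np.ndarray,
    y_train,
    x_val: np.ndarray,
    y_val,
    config: TrainConfig = TrainConfig(),
) -> dict:
    """Train ``spec`` in place; returns the history dict.

    ``y_*`` are string class labels. History holds per-epoch train loss,
    validation weighted F1 and the learning rate in effect.
    """
    x_train = np.asarray(x_train)
    x_val = np.asarray(x_val)
    y_train = np.asarray([str(c) for c in y_train])
    y_val_labels = [str(c) for c in y_val]
    if len(set(y_train)) < 2:
        raise ValueError("training set holds a single class")

    rng = np.random.default_rng(config.seed)
    if config.undersample:
        keep = undersample(y_train, rng)
        x_train, y_train = x_train[keep], y_train[keep]
    y_idx = _encode(y_train)
    dtype = spec.layers[-1].params["W"].dtype
    x_train = x_train.astype(dtype)
    x_val = x_val.astype(dtype)

    lr = spec.learning_rate
    velocity: list[dict[str, np.ndarray]] | None = None
    if config.momentum:
        velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in spec.layers
        ]

    history: dict = {"train_loss": [], "val_f1": [], "lr": []}
    best_f1 = -np.inf
    best_weights = spec.get_weights()
    since_best = 0
    since_lr = 0
    n = len(x_train)
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            logits = spec.forward(x_train[idx], training=True, rng=rng)
            loss, dlogits = softmax_xent(logits, y_idx[idx])
            losses.append(loss + spec.penalty())
            spec.backward(dlogits)
            for li, layer in enumerate(spec.layers):
                skip = getattr(layer, "non_trainable", ())
                for key, grad in layer.grads.items():
                    if key in skip:
                        continue
                    if spec.clipvalue is not None:
                        grad = np.clip(grad, -spec.clipvalue, spec.clipvalue)
                    if velocity is not None:
                        v = velocity[li][key]
                        v *= config.momentum
                        v -= lr * grad
                        layer.params[key] += v
                    else:
                        layer.params[key] -= lr * grad
        val_f1 = _val_f1(spec, x_val, y_val_labels)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_f1"].append(float(val_f1))
        history["lr"].append(float(lr))
        if val_f1 > best_f1 + config.min_delta:
            best_f1 = val_f1
            best_weights = spec.get_weights()
            since_best = 0
            since_lr = 0
        else:
            since_best += 1
            since_lr += 1
        if config.stop_at_f1 is not None and best_f1 >= config.stop_at_f1:
            break
        if since_best >= config.early_stop_patience:
            break
        if since_lr >= config.lr_patience:
            lr *= config.lr_factor
            since_lr = 0
    spec.set_weights(best_weights)
    history["best_val_f1"] = float(best_f1)
    return history


def predict_proba(spec: ModelSpec, window: np.ndarray) -> np.ndarray:
    """Probabilities for one (400, 6) window or an (N, 400, 6) batch."""
    return spec.predict_proba(window)
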