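"""Shared minibatch training loop with early stopping.

Used by both the per-event EverFlow classifier and the patient-level residual
classifiers: shuffled minibatches, weighted softmax cross-entropy, a
validation split carved from the training data, early stop on validation-loss
plateau (patience in epochs), best-weights restoration, and a recorded
per-epoch history. Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DegenerateTraining
from .layers import (
    Layer,
    load_state_dict,
    set_training,
    softmax,
    softmax_cross_entropy,
    state_dict,
)
from .optim import make_optimizer, trainable_parameters


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i,
                "train_loss": tl,
                "val_loss": vl,
                "val_accuracy": va,
            }
            for i, (tl, vl, va) in enumerate(
                zip(self.train_loss, self.val_loss, self.val_accuracy)
            )
        ]


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """w_c proportional to 1/count_c, normalized to mean 1 over present classes."""
    counts = np.bincount(y, minlength=n_classes).astype(float)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = 1.0 / counts[present]
    w[present] /= w[present].mean()
    return w


def predict_proba(net: Layer, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
    """Class probabilities in eval mode, batched for large inputs."""
    set_training(net, False)
    out = []
    for i in range(0, len(X), batch_size):
        out.append(softmax(net.forward(X[i : i + batch_size])))
    return np.concatenate(out)


def fit_classifier(
    net: Layer,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    *,
    lr: float = 5e-3,
    max_epochs: int = 75,
    batch_size: int = 256,
    seed: int = 0,
    optimizer: str = "ranger",
    class_weighting: str | None = "inverse-frequency",
    val_fraction: float = 0.1,
    patience: int = 10,
    min_delta: float = 1e-4,
) -> TrainingHistory:
    """Train ``net`` in place; returns the per-epoch history."""
    y = np.asarray(y, dtype=np.intp)
    present = np.unique(y)
    if len(present) < 2:
        raise DegenerateTraining(
            f"need at least 2 classes to train, got {len(present)}"
        )
    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0 or len(np.unique(y[train_idx])) < 2:
        raise DegenerateTraining("training split degenerate after validation carve-out")
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    weights = (
        inverse_frequency_weights(ytr, n_classes)
        if class_weighting == "inverse-frequency"
        else None
    )
    opt = make_optimizer(optimizer, trainable_parameters(net), lr)
    history = TrainingHistory()
    best_val = np.inf
    best_state = state_dict(net)
    since_best = 0

    for epoch in range(max_epochs):
        set_training(net, True)
        order = rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            if len(idx) < 2:  # batch norm needs > 1 sample
                continue
            logits = net.forward(Xtr[idx])
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx], weights)
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))

        if n_val:
            # validation loss is unweighted: the carve-out may miss classes
            proba = predict_proba(net, Xval)
            vloss, _ = softmax_cross_entropy(
                np.log(np.clip(proba, 1e-12, None)), yval
            )
            vacc = float((proba.argmax(axis=1) == yval).mean())
        else:
            vloss, vacc = history.train_loss[-1], np.nan
        history.val_loss.append(float(vloss))
        history.val_accuracy.append(vacc)

        if vloss < best_val - min_delta:
            best_val = vloss
            best_state = state_dict(net)
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = max_epochs - 1

    load_state_dict(net, best_state)
    set_training(net, False)
    return history
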