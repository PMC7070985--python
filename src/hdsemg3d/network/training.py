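"""Mini-batch SGD training with plateau-halving learning-rate schedule.

The recipe: plain stochastic gradient descent on the categorical
cross-entropy of the softmax output, initial learning rate 0.1, halved
whenever the loss has not improved for ``halve_patience`` consecutive
iterations (an *iteration* is one epoch by default; configurable to one
batch).  Batch normalization precedes every non-linearity and dropout
(p = 0.5) regularizes the two hidden fully connected layers; both are part
of the network spec rather than the trainer.

Everything is deterministic given the config seed: weight initialization,
epoch shuffling, and dropout masks all draw from one
``numpy.random.Generator``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..cubes import CubeDataset
from .model import Model
from .spec import NetworkSpec

__all__ = [
    "TrainingConfig", "TrainedModel", "train", "predict",
    "lr_schedule", "cross_entropy", "binary_cross_entropy",
]


@dataclass
class TrainingConfig:
    lr0: float = 0.1
    halve_patience: int = 10
    batch_size: int = 32
    max_epochs: int = 30
    seed: int = 0
    momentum: float = 0.0
    bn_mode: str = "channel"
    lr_step: str = "epoch"  # or "batch"

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.halve_patience < 1:
            raise ValueError("halve_patience must be >= 1")


def lr_schedule(loss_history, current_lr: float, patience: int = 10) -> float:
    """Halve the rate when the last ``patience`` losses show no improvement.

    "No improvement" means the minimum over the trailing ``patience``
    entries is >= the minimum over everything before them.  With fewer than
    ``patience + 1`` entries there is no earlier minimum to beat, so the
    rate is unchanged.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    history = list(loss_history)
    if not history:
        raise ValueError("empty loss history")
    if len(history) <= patience:
        return current_lr
    if min(history[-patience:]) >= min(history[:-patience]):
        return current_lr / 2.0
    return current_lr


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax outputs."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def binary_cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Two-class form of the loss, kept for G = 2 problems."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.clip(np.asarray(y_pred, dtype=np.float64), 1e-12, 1 - 1e-12)
    return float(-np.mean(y_true * np.log(y_pred)
                          + (1 - y_true) * np.log(1 - y_pred)))


def _as_model_input(x: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """Match cube arrays to the spec input (squeeze l=1 for 2D nets)."""
    want = len(spec.input_shape)
    if x.ndim - 1 == want:
        return x
    if x.ndim - 1 == want + 1 and x.shape[1] == 1:
        return x[:, 0]
    raise ValueError(
        f"input shape {x.shape[1:]} incompatible with spec input "
        f"{spec.input_shape}"
    )


class TrainedModel:
    """Handle around a fitted :class:`Model` with training history."""

    def __init__(self, model: Model, spec: NetworkSpec,
                 cfg: TrainingConfig, loss_history: list[float],
                 lr_history: list[float], log: list[str]) -> None:
        self.model = model
        self.spec = spec
        self.cfg = cfg
        self.loss_history = loss_history
        self.lr_history = lr_history
        self.log = log

    def predict(self, cubes) -> tuple[np.ndarray, np.ndarray]:
        """Per-cube ``(labels, probability matrix)``.

        Labels are the argmax of the softmax output; exact ties resolve to
        the smallest class index.
        """
        x = cubes.cubes if isinstance(cubes, CubeDataset) else np.asarray(cubes)
        x = _as_model_input(x, self.spec)
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"cube shape {x.shape[1:]} != spec input {self.spec.input_shape}"
            )
        probs = self.model.predict_proba(x)
        return probs.argmax(axis=1), probs

    def save(self, path: str | Path) -> Path:
        import hashlib

        path = Path(path)
        np.savez(path, **self.model.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "spec_sha256": hashlib.sha256(
                self.spec.to_yaml().encode()).hexdigest(),
            "spec_yaml": self.spec.to_yaml(),
            "config": self.cfg.__dict__,
            "loss_history": self.loss_history,
            "lr_history": self.lr_history,
            "log": self.log,
        }))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = NetworkSpec.from_yaml(meta["spec_yaml"])
        cfg = TrainingConfig(**meta["config"])
        model = Model(spec, np.random.default_rng(cfg.seed), cfg.bn_mode)
        with np.load(path.with_suffix(".npz")
                     if path.suffix != ".npz" else path) as f:
            model.load_state_dict(dict(f))
        return cls(model, spec, cfg, meta["loss_history"],
                   meta["lr_history"], meta["log"])


def train(spec: NetworkSpec, train_set: CubeDataset,
          cfg: TrainingConfig) -> TrainedModel:
    """Fit the spec to a labeled cube set with SGD.

    Deterministic given ``cfg.seed``.  A gesture class absent from the
    training set is recorded as a warning in the run log, not an error.
    """
    G = spec.n_classes
    labels = train_set.labels
    if labels.min() < 0 or labels.max() >= G:
        raise ValueError(f"labels must lie in [0, {G})")
    log: list[str] = []
    missing = sorted(set(range(G)) - set(labels.tolist()))
    if missing:
        msg = f"classes absent from training data: {missing}"
        warnings.warn(msg)
        log.append(f"warning: {msg}")

    rng = np.random.default_rng(cfg.seed)
    model = Model(spec, rng, bn_mode=cfg.bn_mode)
    x_all = _as_model_input(np.asarray(train_set.cubes, dtype=np.float32), spec)
    velocity = {id(p): np.zeros_like(p)
                for _, _, p in model.trainable()} if cfg.momentum else None

    lr = cfg.lr0
    best = np.inf
    since_improve = 0
    loss_history: list[float] = []
    lr_history: list[float] = []
    n = len(train_set)

    def sgd_step() -> None:
        for layer, name, p in model.trainable():
            g = layer.grads[name]
            if velocity is not None:
                v = velocity[id(p)]
                v *= cfg.momentum
                v -= lr * g
                p += v
            else:
                p -= lr * g

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x_all[idx], labels[idx]
            logits = model.forward(xb, training=True)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=1, keepdims=True)
            loss = cross_entropy(probs, yb)
            batch_losses.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits.astype(np.float32))
            sgd_step()
            if cfg.lr_step == "batch":
                if loss < best - 1e-12:
                    best, since_improve = loss, 0
                else:
                    since_improve += 1
                if since_improve >= cfg.halve_patience:
                    lr /= 2.0
                    since_improve = 0
        epoch_loss = float(np.mean(batch_losses))
        loss_history.append(epoch_loss)
        lr_history.append(lr)
        if cfg.lr_step == "epoch":
            if epoch_loss < best - 1e-12:
                best, since_improve = epoch_loss, 0
            else:
                since_improve += 1
            if since_improve >= cfg.halve_patience:
                lr = lr_schedule(loss_history, lr, cfg.halve_patience)
                since_improve = 0
    log.append(f"trained {cfg.max_epochs} epochs on {n} cubes, final loss "
               f"{loss_history[-1]:.4f}, final lr {lr:.4g}")
    return TrainedModel(model, spec, cfg, loss_history, lr_history, log)


def predict(model: TrainedModel, cubes) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(cubes)
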