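"""Instantiate a trainable model from a :class:`NetworkSpec`."""

from __future__ import annotations

import numpy as np

from . import layers as L
from .spec import NetworkSpec, propagate_shapes

__all__ = ["Model"]


class Model:
    """A concrete numpy network built from a declarative spec.

    ``bn_mode="channel"`` instantiates the spec as written (batch norm after
    each conv/dense, per-channel parameters).  ``bn_mode="activation"``
    instead places per-activation batch norm *before* every conv/dense layer
    (including the input) and drops the spec's own batch-norm entries; this
    is the instantiation matching the ``bn-activation`` count convention.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 bn_mode: str = "channel") -> None:
        if bn_mode not in ("channel", "activation"):
            raise ValueError(f"unknown bn_mode {bn_mode!r}")
        self.spec = spec
        self.bn_mode = bn_mode
        self.layers: list[L.Layer] = []
        shapes = propagate_shapes(spec)
        inputs = [tuple(spec.input_shape)] + shapes[:-1]
        for lspec, in_shape in zip(spec.layers, inputs):
            kind = lspec.kind
            if kind in ("conv3d", "conv2d", "dense") and bn_mode == "activation":
                self.layers.append(L.BatchNorm(in_shape, mode="activation"))
            if kind == "conv3d":
                self.layers.append(L.Conv3D(in_shape[-1], lspec.n_kernels,
                                            lspec.kernel, lspec.padding, rng))
            elif kind == "conv2d":
                self.layers.append(L.Conv2D(in_shape[-1], lspec.n_kernels,
                                            lspec.kernel, lspec.padding, rng))
            elif kind == "dense":
                self.layers.append(L.Dense(in_shape[0], lspec.n_units, rng))
            elif kind == "batchnorm":
                if bn_mode == "channel":
                    self.layers.append(L.BatchNorm(in_shape, mode="channel"))
            elif kind == "relu":
                self.layers.append(L.ReLU())
            elif kind == "pool":
                pool_cls = (L.AvgPoolTemporal if getattr(lspec, "op", "max")
                            == "avg" else L.MaxPoolTemporal)
                self.layers.append(pool_cls(lspec.s))
            elif kind == "dropout":
                self.layers.append(L.Dropout(lspec.p, rng))
            elif kind == "flatten":
                self.layers.append(L.Flatten())
            elif kind == "softmax":
                pass  # folded into the loss / predict_proba
            else:
                raise ValueError(f"unknown layer kind {kind!r}")

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch shaped ``(N, *input_shape)``."""
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, evaluated in inference mode."""
        chunks = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], training=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            chunks.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(chunks)

    # -- parameter bookkeeping -------------------------------------------
    def trainable(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def n_trainable_params(self) -> int:
        return sum(p.size for _, _, p in self.trainable())

    def n_params(self, include_statistics: bool = False) -> int:
        n = self.n_trainable_params()
        if include_statistics:
            for layer in self.layers:
                if isinstance(layer, L.BatchNorm):
                    n += layer.moving_mean.size + layer.moving_var.size
        return n

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p
            if isinstance(layer, L.BatchNorm):
                state[f"{i}.moving_mean"] = layer.moving_mean
                state[f"{i}.moving_var"] = layer.moving_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"])
            if isinstance(layer, L.BatchNorm):
                layer.moving_mean = np.asarray(state[f"{i}.moving_mean"])
                layer.moving_var = np.asarray(state[f"{i}.moving_var"])
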