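"""Trainable layers: vectorized numpy forward/backward passes.

Convolutions are evaluated with an im2col strategy: a strided sliding-window
view of the (zero-padded) input is contracted against the kernel tensor with
a single ``tensordot``.  The nested-loop reference implementation in
:mod:`hdsemg3d.network.reference` is kept deliberately independent of this
code path and serves as its correctness oracle.

All layers operate on channels-last batches: ``(N, l, h, w, C)`` for 3D,
``(N, h, w, C)`` for 2D, ``(N, F)`` for dense.  Weights are float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv3D", "Conv2D", "Dense", "BatchNorm", "ReLU",
    "MaxPoolTemporal", "Dropout", "Flatten",
]


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3D(Layer):
    """3D convolution, stride 1, zero padding ``(pt, ph, pw)``.

    Kernel tensor ``W`` has shape ``(d, k1, k2, C_in, F)``; the operation is
    a sliding inner product (cross-correlation, the deep-learning
    convention).
    """

    def __init__(self, c_in: int, n_kernels: int,
                 kernel: tuple[int, int, int],
                 padding: tuple[int, int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        d, k1, k2 = kernel
        fan_in = d * k1 * k2 * c_in
        self.kernel = kernel
        self.padding = padding
        self.params = {
            "W": _he_uniform(rng, (d, k1, k2, c_in, n_kernels), fan_in),
            "b": np.zeros(n_kernels, dtype=np.float32),
        }

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pt, ph, pw = self.padding
        if pt == ph == pw == 0:
            return x
        return np.pad(x, ((0, 0), (pt, pt), (ph, ph), (pw, pw), (0, 0)))

    def _patches(self, xp: np.ndarray) -> np.ndarray:
        d, k1, k2 = self.kernel
        sw = np.lib.stride_tricks.sliding_window_view(xp, (d, k1, k2),
                                                      axis=(1, 2, 3))
        return sw  # (N, l', h', w', C, d, k1, k2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._xp = self._pad(np.asarray(x, dtype=np.float32))
        patches = self._patches(self._xp)
        out = np.tensordot(patches, self.params["W"],
                           axes=([5, 6, 7, 4], [0, 1, 2, 3]))
        return out + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        d, k1, k2 = self.kernel
        patches = self._patches(self._xp)
        # dW: contract batch and output positions
        dW = np.tensordot(patches, dout, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        # (C, d, k1, k2, F) -> (d, k1, k2, C, F)
        self.grads["W"] = np.moveaxis(dW, 0, 3).astype(np.float32)
        self.grads["b"] = dout.sum(axis=(0, 1, 2, 3)).astype(np.float32)
        dxp = np.zeros_like(self._xp)
        lo, ho, wo = dout.shape[1:4]
        for p in range(d):
            for q in range(k1):
                for r in range(k2):
                    # (N,l',h',w',F) @ (F,C)
                    dxp[:, p:p + lo, q:q + ho, r:r + wo, :] += (
                        dout @ W[p, q, r].T
                    )
        pt, ph, pw = self.padding
        del self._xp
        return dxp[:, pt:dxp.shape[1] - pt or None,
                   ph:dxp.shape[2] - ph or None,
                   pw:dxp.shape[3] - pw or None, :]


class Conv2D(Layer):
    """2D convolution, stride 1, zero padding ``(ph, pw)``."""

    def __init__(self, c_in: int, n_kernels: int,
                 kernel: tuple[int, int], padding: tuple[int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        k1, k2 = kernel
        self.kernel = kernel
        self.padding = padding
        self.params = {
            "W": _he_uniform(rng, (k1, k2, c_in, n_kernels), k1 * k2 * c_in),
            "b": np.zeros(n_kernels, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        ph, pw = self.padding
        x = np.asarray(x, dtype=np.float32)
        self._xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0))) \
            if ph or pw else x
        sw = np.lib.stride_tricks.sliding_window_view(
            self._xp, self.kernel, axis=(1, 2))  # (N,h',w',C,k1,k2)
        out = np.tensordot(sw, self.params["W"],
                           axes=([4, 5, 3], [0, 1, 2]))
        return out + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        k1, k2 = self.kernel
        sw = np.lib.stride_tricks.sliding_window_view(
            self._xp, self.kernel, axis=(1, 2))
        dW = np.tensordot(sw, dout, axes=([0, 1, 2], [0, 1, 2]))
        # (C, k1, k2, F) -> (k1, k2, C, F)
        self.grads["W"] = np.moveaxis(dW, 0, 2).astype(np.float32)
        self.grads["b"] = dout.sum(axis=(0, 1, 2)).astype(np.float32)
        dxp = np.zeros_like(self._xp)
        ho, wo = dout.shape[1:3]
        for q in range(k1):
            for r in range(k2):
                dxp[:, q:q + ho, r:r + wo, :] += dout @ W[q, r].T
        ph, pw = self.padding
        del self._xp
        return dxp[:, ph:dxp.shape[1] - ph or None,
                   pw:dxp.shape[2] - pw or None, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": _he_uniform(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"].T


class BatchNorm(Layer):
    """Batch normalization with per-channel or per-activation parameters.

    ``mode="channel"`` normalizes over every axis except the last (the
    standard convolutional convention); ``mode="activation"`` normalizes
    over the batch axis only, giving each activation its own gamma/beta.
    Inference uses exponential moving statistics.
    """

    def __init__(self, feature_shape: tuple[int, ...], mode: str = "channel",
                 momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        if mode not in ("channel", "activation"):
            raise ValueError(f"unknown batchnorm mode {mode!r}")
        self.mode = mode
        self.momentum = momentum
        self.eps = eps
        shape = (feature_shape[-1],) if mode == "channel" else tuple(feature_shape)
        self.params = {
            "gamma": np.ones(shape, dtype=np.float32),
            "beta": np.zeros(shape, dtype=np.float32),
        }
        self.moving_mean = np.zeros(shape, dtype=np.float32)
        self.moving_var = np.ones(shape, dtype=np.float32)

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return tuple(range(x.ndim - 1)) if self.mode == "channel" else (0,)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean = (m * self.moving_mean + (1 - m) * mean).astype(np.float32)
            self.moving_var = (m * self.moving_var + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.moving_mean, self.moving_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = self._axes(dout)
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        self.grads["gamma"] = (dout * xhat).sum(axis=axes).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=axes).astype(np.float32)
        dxhat = dout * self.params["gamma"]
        dx = (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=(self.mode == "activation"))
            - xhat * (dxhat * xhat).sum(axis=axes,
                                        keepdims=(self.mode == "activation"))
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPoolTemporal(Layer):
    """Max pool of size ``s`` along the temporal axis only (ceil semantics).

    The input is padded with -inf to a multiple of ``s``, so a trailing
    window shorter than ``s`` still produces an output frame.
    """

    def __init__(self, s: int) -> None:
        super().__init__()
        self.s = s

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, l = x.shape[0], x.shape[1]
        lp = -(-l // self.s)
        pad = lp * self.s - l
        self._l = l
        if pad:
            pad_width = [(0, 0), (0, pad)] + [(0, 0)] * (x.ndim - 2)
            x = np.pad(x, pad_width, constant_values=-np.inf)
        xr = x.reshape(n, lp, self.s, *x.shape[2:])
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, lp = dout.shape[0], dout.shape[1]
        dxr = np.zeros((n, lp, self.s, *dout.shape[2:]), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, np.newaxis],
                          dout[:, :, np.newaxis], axis=2)
        dx = dxr.reshape(n, lp * self.s, *dout.shape[2:])
        return dx[:, :self._l]


class AvgPoolTemporal(Layer):
    """Mean pool of size ``s`` along the temporal axis only (ceil semantics).

    The trailing truncated window averages over its actual extent.
    """

    def __init__(self, s: int) -> None:
        super().__init__()
        self.s = s

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, l = x.shape[0], x.shape[1]
        lp = -(-l // self.s)
        pad = lp * self.s - l
        self._l = l
        if pad:
            pad_width = [(0, 0), (0, pad)] + [(0, 0)] * (x.ndim - 2)
            x = np.pad(x, pad_width)
        xr = x.reshape(n, lp, self.s, *x.shape[2:])
        # per-window divisor: truncated last window averages its own extent
        counts = np.full(lp, self.s, dtype=np.float32)
        if pad:
            counts[-1] = self.s - pad
        self._counts = counts.reshape(1, lp, *([1] * (x.ndim - 2)))
        return xr.sum(axis=2) / self._counts

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, lp = dout.shape[0], dout.shape[1]
        dxr = np.repeat((dout / self._counts)[:, :, np.newaxis], self.s,
                        axis=2)
        dx = dxr.reshape(n, lp * self.s, *dout.shape[2:])
        return dx[:, :self._l]


class Dropout(Layer):
    """Inverted dropout; the mask stream comes from the model's RNG."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)
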