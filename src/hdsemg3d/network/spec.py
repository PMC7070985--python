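"""Declarative network specs, shape propagation, and analytic weight counts.

The classifier family is fixed: three convolutional layers (32/64/64
kernels, all 3x3x3 in the spatiotemporal variant, 3x3 in the per-frame
ablation), batch normalization before every non-linearity, temporal-only
max-pooling after the second and third convolutions, two fully connected
layers (512/128) with dropout 0.5, and a G-way softmax.  A
:class:`NetworkSpec` is a plain layer list from which both the trainable
model and the analytic parameter count are derived, so the two can never
drift apart.

Spatiotemporal variant (cube input ``l x h x w x 1``)::

    conv3d(32, 3x3x3) -> BN -> relu
    conv3d(64, 3x3x3, pad 0x1x1) -> BN -> relu -> pool(s x 1 x 1)
    conv3d(64, 3x3x3, pad 0x1x1) -> BN -> relu -> pool(s x 1 x 1)
    flatten -> dense(512) -> BN -> relu -> dropout(0.5)
            -> dense(128) -> BN -> relu -> dropout(0.5)
            -> dense(G) -> softmax

The per-frame (2D) ablation removes the temporal dimension of kernels,
padding, and pooling; the degenerate 1x1 pooling is omitted.

Parameter-count conventions
---------------------------
How many "weights to be learnt" a network has depends on bookkeeping
choices that published totals rarely state.  :func:`count_parameters`
therefore takes a convention tag:

``none``
    Conv/dense weights and biases only.
``bn-channel``
    Plus 2 trainable parameters (gamma, beta) per normalized channel for
    each batch-norm layer in the spec (the usual modern convention).
``bn-channel-full``
    As ``bn-channel`` plus the 2 non-trainable moving statistics.
``bn-activation``
    Batch normalization placed before every conv/dense layer (including
    the network input), with gamma/beta per input activation: 2 trainable
    parameters per element of each weighted layer's input tensor.  This is
    the convention under which the reference weight counts for this
    architecture family are reproduced exactly (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Conv3DSpec", "Conv2DSpec", "PoolSpec", "BatchNormSpec", "ReLUSpec",
    "DropoutSpec", "FlattenSpec", "DenseSpec", "SoftmaxSpec", "NetworkSpec",
    "build_3d_cnn", "build_2d_cnn", "propagate_shapes", "count_parameters",
    "COUNT_CONVENTIONS",
]

COUNT_CONVENTIONS = ("none", "bn-channel", "bn-channel-full", "bn-activation")


@dataclass(frozen=True)
class Conv3DSpec:
    n_kernels: int
    kernel: tuple[int, int, int] = (3, 3, 3)  # (d, k, k) temporal first
    padding: tuple[int, int, int] = (0, 0, 0)
    kind: str = "conv3d"


@dataclass(frozen=True)
class Conv2DSpec:
    n_kernels: int
    kernel: tuple[int, int] = (3, 3)
    padding: tuple[int, int] = (0, 0)
    kind: str = "conv2d"


@dataclass(frozen=True)
class PoolSpec:
    """Temporal-only pool of size s x 1 x 1, ceil semantics.

    Boundary windows are truncated, so a temporal extent of 1 survives
    unchanged instead of being annihilated.  ``op`` selects max (default,
    the common choice in spatiotemporal networks: it retains the temporal
    position of salient activation, which carries the motion cue) or
    average pooling.
    """

    s: int
    op: str = "max"
    kind: str = "pool"


@dataclass(frozen=True)
class BatchNormSpec:
    kind: str = "batchnorm"


@dataclass(frozen=True)
class ReLUSpec:
    kind: str = "relu"


@dataclass(frozen=True)
class DropoutSpec:
    p: float = 0.5
    kind: str = "dropout"


@dataclass(frozen=True)
class FlattenSpec:
    kind: str = "flatten"


@dataclass(frozen=True)
class DenseSpec:
    n_units: int
    kind: str = "dense"


@dataclass(frozen=True)
class SoftmaxSpec:
    kind: str = "softmax"


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus the input tensor shape (no batch axis)."""

    input_shape: tuple[int, ...]
    layers: tuple = ()
    name: str = "network"

    @property
    def n_classes(self) -> int:
        for layer in reversed(self.layers):
            if layer.kind == "dense":
                return layer.n_units
        raise ValueError("spec has no dense layer")

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in layer.__dict__.items()}
                for layer in self.layers
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        registry = {
            "conv3d": Conv3DSpec, "conv2d": Conv2DSpec, "pool": PoolSpec,
            "batchnorm": BatchNormSpec, "relu": ReLUSpec,
            "dropout": DropoutSpec, "flatten": FlattenSpec,
            "dense": DenseSpec, "softmax": SoftmaxSpec,
        }
        layers = []
        for entry in doc["layers"]:
            entry = dict(entry)
            kind = entry.pop("kind")
            entry = {k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in entry.items()}
            layers.append(registry[kind](**entry))
        return cls(input_shape=tuple(doc["input_shape"]),
                   layers=tuple(layers), name=doc.get("name", "network"))


class ShapeError(ValueError):
    """A layer's output shape collapsed to a non-positive size."""


def _conv_out(size: int, k: int, pad: int) -> int:
    return size + 2 * pad - k + 1


def propagate_shapes(spec: NetworkSpec) -> list[tuple[int, ...]]:
    """Output shape after every layer; raises :class:`ShapeError` on collapse."""
    shape = tuple(spec.input_shape)
    out = []
    for idx, layer in enumerate(spec.layers):
        if layer.kind == "conv3d":
            l, h, w, _ = shape
            d, k1, k2 = layer.kernel
            pt, ph, pw = layer.padding
            shape = (_conv_out(l, d, pt), _conv_out(h, k1, ph),
                     _conv_out(w, k2, pw), layer.n_kernels)
        elif layer.kind == "conv2d":
            h, w, _ = shape
            k1, k2 = layer.kernel
            ph, pw = layer.padding
            shape = (_conv_out(h, k1, ph), _conv_out(w, k2, pw),
                     layer.n_kernels)
        elif layer.kind == "pool":
            shape = (math.ceil(shape[0] / layer.s),) + shape[1:]
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            shape = (layer.n_units,)
        else:  # batchnorm / relu / dropout / softmax preserve shape
            shape = shape
        if any(s < 1 for s in shape):
            raise ShapeError(
                f"layer {idx} ({layer.kind}) collapses shape to {shape}; "
                f"input too small for this architecture"
            )
        out.append(shape)
    return out


def build_3d_cnn(
    input_shape: tuple[int, int, int, int],
    pool_s: int,
    G: int,
    conv_channels: tuple[int, int, int] = (32, 64, 64),
    dense_units: tuple[int, int] = (512, 128),
    dropout_p: float = 0.5,
    pool_op: str = "max",
    name: str = "cnn3d",
) -> NetworkSpec:
    """Spatiotemporal classifier spec for an ``l x h x w x 1`` cube input.

    ``pool_s`` is tied to the sampling rate of the source data (2 for
    1000 Hz grids, 4 for 2048 Hz grids) so that temporal resolution after
    pooling is comparable.  Raises :class:`ShapeError` if ``l`` is too small
    for the temporal trace to stay positive.
    """
    c1, c2, c3 = conv_channels
    u1, u2 = dense_units
    layers = (
        Conv3DSpec(c1, (3, 3, 3)), BatchNormSpec(), ReLUSpec(),
        Conv3DSpec(c2, (3, 3, 3), padding=(0, 1, 1)), BatchNormSpec(), ReLUSpec(),
        PoolSpec(pool_s, pool_op),
        Conv3DSpec(c3, (3, 3, 3), padding=(0, 1, 1)), BatchNormSpec(), ReLUSpec(),
        PoolSpec(pool_s, pool_op),
        FlattenSpec(),
        DenseSpec(u1), BatchNormSpec(), ReLUSpec(), DropoutSpec(dropout_p),
        DenseSpec(u2), BatchNormSpec(), ReLUSpec(), DropoutSpec(dropout_p),
        DenseSpec(G), SoftmaxSpec(),
    )
    spec = NetworkSpec(input_shape=tuple(input_shape), layers=layers, name=name)
    propagate_shapes(spec)  # fail fast on temporal collapse
    return spec


def build_2d_cnn(
    input_shape: tuple[int, int, int],
    G: int,
    conv_channels: tuple[int, int, int] = (32, 64, 64),
    dense_units: tuple[int, int] = (512, 128),
    dropout_p: float = 0.5,
    name: str = "cnn2d",
) -> NetworkSpec:
    """Per-frame ablation: temporal kernel/padding/pooling dimensions removed."""
    c1, c2, c3 = conv_channels
    u1, u2 = dense_units
    layers = (
        Conv2DSpec(c1, (3, 3)), BatchNormSpec(), ReLUSpec(),
        Conv2DSpec(c2, (3, 3), padding=(1, 1)), BatchNormSpec(), ReLUSpec(),
        Conv2DSpec(c3, (3, 3), padding=(1, 1)), BatchNormSpec(), ReLUSpec(),
        FlattenSpec(),
        DenseSpec(u1), BatchNormSpec(), ReLUSpec(), DropoutSpec(dropout_p),
        DenseSpec(u2), BatchNormSpec(), ReLUSpec(), DropoutSpec(dropout_p),
        DenseSpec(G), SoftmaxSpec(),
    )
    spec = NetworkSpec(input_shape=tuple(input_shape), layers=layers, name=name)
    propagate_shapes(spec)
    return spec


def count_parameters(spec: NetworkSpec, convention: str = "bn-channel") -> int:
    """Analytic count of the network's parameters under a convention tag."""
    if convention not in COUNT_CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of "
            f"{COUNT_CONVENTIONS}"
        )
    shapes = propagate_shapes(spec)
    inputs = [tuple(spec.input_shape)] + shapes[:-1]
    total = 0
    for layer, in_shape in zip(spec.layers, inputs):
        if layer.kind in ("conv3d", "conv2d"):
            c_in = in_shape[-1]
            total += layer.n_kernels * (int(np.prod(layer.kernel)) * c_in + 1)
            if convention == "bn-activation":
                total += 2 * int(np.prod(in_shape))
        elif layer.kind == "dense":
            n_in = in_shape[0]
            total += n_in * layer.n_units + layer.n_units
            if convention == "bn-activation":
                total += 2 * n_in
        elif layer.kind == "batchnorm":
            if convention == "bn-channel":
                total += 2 * in_shape[-1]
            elif convention == "bn-channel-full":
                total += 4 * in_shape[-1]
    return total
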