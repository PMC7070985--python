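"""Nested-loop reference 3D convolution.

Direct transcription of the defining sum for the value at position
``(x, y, z)`` of output cube ``j``::

    v[j][x, y, z] = f( b[j] + sum_m sum_p sum_q sum_r
                       w[j][m][p, q, r] * u[m][x + p, y + q, z + r] )

where ``u`` are the input cubes, ``w[j]``/``b[j]`` the j-th kernel's weights
and bias, and ``f`` the activation.  Valid-mode (no padding) unless an
explicit zero-padding triple is supplied; stride fixed at 1 x 1 x 1.

This module intentionally avoids the vectorized machinery of
:mod:`hdsemg3d.network.layers` -- it is the independent oracle the fast
implementation is validated against, so clarity wins over speed.  Axis
order is temporal-first ``(depth, height, width)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Kernel3D", "conv3d_reference", "ACTIVATIONS"]

ACTIVATIONS = {
    "identity": lambda v: v,
    "relu": lambda v: max(v, 0.0),
    "sigmoid": lambda v: 1.0 / (1.0 + np.exp(-v)),
    "tanh": np.tanh,
}


@dataclass
class Kernel3D:
    """One 3D kernel: weights ``(d, k1, k2, m_in)`` plus a scalar bias."""

    weights: np.ndarray
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 4:
            raise ValueError("kernel weights must be (d, k1, k2, m_in)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")


def conv3d_reference(
    input_cubes: np.ndarray,
    kernels: list[Kernel3D],
    activation: str = "identity",
    padding: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Evaluate the convolution sum by explicit loops.

    Parameters
    ----------
    input_cubes
        ``(m_in, l, h, w)`` array (the set of cubes from the previous layer).
    kernels
        One :class:`Kernel3D` per output cube; all must share ``m_in`` and
        kernel extent.
    activation
        One of ``identity``, ``relu``, ``sigmoid``, ``tanh``.
    padding
        Zero-padding triple applied to each input cube before the sum.

    Returns
    -------
    ``(n_kernels, l', h', w')`` with ``l' = l + 2*pt - d + 1`` etc.
    """
    u = np.asarray(input_cubes, dtype=np.float64)
    if u.ndim != 4:
        raise ValueError("input_cubes must be (m_in, l, h, w)")
    f = ACTIVATIONS[activation]
    pt, ph, pw = padding
    if pt or ph or pw:
        u = np.pad(u, ((0, 0), (pt, pt), (ph, ph), (pw, pw)))
    m_in, l, h, w = u.shape
    d, k1, k2, m_k = kernels[0].weights.shape
    if m_k != m_in:
        raise ValueError(f"kernel m_in {m_k} != input cube count {m_in}")
    lo, ho, wo = l - d + 1, h - k1 + 1, w - k2 + 1
    if min(lo, ho, wo) < 1:
        raise ValueError(
            f"kernel {d}x{k1}x{k2} larger than (padded) input {l}x{h}x{w}"
        )
    out = np.empty((len(kernels), lo, ho, wo), dtype=np.float64)
    for j, kern in enumerate(kernels):
        if kern.weights.shape != (d, k1, k2, m_in):
            raise ValueError("kernels disagree in shape")
        for x in range(lo):
            for y in range(ho):
                for z in range(wo):
                    acc = kern.bias
                    for m in range(m_in):
                        for p in range(d):
                            for q in range(k1):
                                for r in range(k2):
                                    acc += (kern.weights[p, q, r, m]
                                            * u[m, x + p, y + q, z + r])
                    out[j, x, y, z] = f(acc)
    return out
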