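"""Shared differentiable primitives for the physics operators.

These helpers are written against :mod:`vfpinn.autodiff` but pass plain
ndarrays through untouched, so the forward simulator (pure numpy) and the
training loop (graph-building) share one implementation of every formula.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = ["smooth_relu", "cross3", "triangular_interp", "trapezoid_columns"]


def smooth_relu(x, tau: float = 0.0):
    """max(0, x), optionally mollified to width `tau` (softplus scaling).

    tau = 0 gives the exact hinge (subgradient at 0); tau > 0 gives the C∞
    relaxation ``tau * log(1 + exp(x / tau))`` used while training so that
    gradients do not die when the glottis is closed.
    """
    if tau == 0.0:
        return ad.relu(x)
    # numerically stable softplus: max(x,0) + tau*log1p(exp(-|x|/tau))
    xv = x / tau if ad.is_tensor(x) else np.asarray(x, float) / tau
    return tau * (ad.relu(xv) + ad.log(1.0 + ad.exp(-ad.absolute(xv))))


def cross3(a, b):
    """Cross product on the trailing axis (length 3)."""
    ax, ay, az = a[..., 0], a[..., 1], a[..., 2]
    bx, by, bz = b[..., 0], b[..., 1], b[..., 2]
    return ad.stack([ay * bz - az * by,
                     az * bx - ax * bz,
                     ax * by - ay * bx], axis=-1)


def triangular_interp(coords, values, targets, h):
    """Kernel (hat-function) interpolation of scattered nodal values.

    Parameters
    ----------
    coords : (..., N) node coordinates along the interpolation direction.
    values : (..., N) nodal values.
    targets : (T,) fixed target coordinates **or** (..., T) per-batch targets.
    h : bandwidth (scalar or (...,1) broadcastable); must cover the largest
        node spacing or the normalization collapses.

    Returns (..., T) normalized kernel averages — exact for nodal data that
    is linear between neighbors when `h` equals the local spacing, and a
    local average otherwise.  Differentiable in coords, values and targets.
    """
    c = ad.expand_dims(coords, -2)              # (..., 1, N)
    t = ad.expand_dims(targets, -1)             # (..., T, 1)
    d = ad.absolute(c - t)                      # (..., T, N)
    hh = h if np.isscalar(h) else ad.expand_dims(h, -1)
    w = ad.relu(1.0 - d / hh)
    den = w.sum(axis=-1)
    num = (w * ad.expand_dims(values, -2)).sum(axis=-1)
    # the epsilon keeps value AND gradient bounded if a target ever loses
    # kernel coverage (weights are O(1), so the bias is ~1e-6 relative)
    return num / (den + 1e-6)


def trapezoid_columns(values, coords):
    """Trapezoid rule ∫ values d(coords) along the trailing axis."""
    dv = coords[..., 1:] - coords[..., :-1]
    mid = 0.5 * (values[..., 1:] + values[..., :-1])
    return (mid * dv).sum(axis=-1)
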