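"""Differentiable 1D Bernoulli glottal-flow solver.

The glottal channel is sliced into ``n_sections`` horizontal sections between
the inferior and superior margins of the (deformed) medial surface.  With the
left–right symmetry assumption the local gap is ``2 max(0, -x)`` and the
section area its spanwise integral.  Flow separation is pinned at the
minimum-area section: the flow rate follows from the separation condition

    Q = sqrt(2 P_sub / rho_air) * A_min,

and the intraglottal pressure upstream of separation from Bernoulli,

    P(y) = P_sub - 1/2 rho_air (Q / A(y))^2,

with zero gage pressure downstream.  Note the algebraic identity: at the
separation section the two relations give P = 0 exactly.

All operators run on plain ndarrays (forward simulation) or autodiff tensors
(training); minima/hinges take a temperature ``tau`` for smooth relaxation
during training and are exact at ``tau = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .ops import smooth_relu, triangular_interp, trapezoid_columns

__all__ = ["FlowParams", "FlowState", "section_areas", "min_area",
           "flow_rate", "pressure_profile"]


@dataclass
class FlowParams:
    """Flow constants. Defaults: P_sub = 1.0 kPa, rho_air = 1.1 kg/m³,
    100 sections — the canonical phonation conditions of the study setup."""

    P_sub: float = 1000.0
    rho_air: float = 1.1
    n_sections: int = 100
    area_floor: float = 1e-8       # m²; keeps 1/A² finite through closure
    tau_min: float = 0.0           # smooth-min temperature (m²); 0 = exact
    tau_gap: float = 0.0           # hinge mollification width (m); 0 = exact

    def __post_init__(self):
        if self.P_sub < 0:
            raise ValueError("subglottal pressure must be >= 0")
        if self.rho_air <= 0:
            raise ValueError("air density must be positive")
        if self.n_sections < 2:
            raise ValueError("need at least 2 flow sections")
        if self.area_floor <= 0:
            raise ValueError("area floor must be positive")


@dataclass
class FlowState:
    """Evaluated flow solution at one instant (numpy arrays)."""

    y_sections: np.ndarray
    areas: np.ndarray
    Q: float
    pressures: np.ndarray
    i_sep: int


def section_areas(X_grid, params: FlowParams):
    """Section heights and areas from the deformed medial-surface grid.

    Parameters
    ----------
    X_grid : (..., R, C, 3) medial-surface node positions; rows run
        inferior → superior, columns anterior → posterior.
    params : FlowParams.

    Returns
    -------
    y_sections : (..., S) equispaced heights across the current
        inferior–superior extent of the surface.
    areas : (..., S) spanwise-integrated gap, clamped to the area floor.

    The gap field ``2 max(0, -x)`` is sampled at each section by hat-kernel
    interpolation along each spanwise column (bandwidth = current row
    spacing), then integrated over the span with the trapezoid rule on the
    current column positions.  Everything is (piecewise) differentiable in
    the node positions.
    """
    if ad.asarray(X_grid).ndim < 3 or ad.asarray(X_grid).shape[-1] != 3:
        raise ValueError("X_grid must have shape (..., R, C, 3)")
    R = ad.asarray(X_grid).shape[-3]
    S = params.n_sections
    x = X_grid[..., 0]
    y = X_grid[..., 1]
    z = X_grid[..., 2]
    gap = 2.0 * smooth_relu(-x, params.tau_gap)          # (..., R, C)

    # flatten (R, C) -> surface axis for the global extent
    flat_y = y.reshape(ad.asarray(y).shape[:-2] + (-1,))
    y_lo = flat_y.min(axis=-1)
    y_hi = flat_y.max(axis=-1)
    frac = np.linspace(0.0, 1.0, S)
    extent = y_hi - y_lo
    y_sec = ad.expand_dims(y_lo, -1) + ad.expand_dims(extent, -1) * frac  # (..., S)
    h = extent / (R - 1) * 1.25                            # kernel bandwidth

    # interpolate gap to sections per column: move column axis in front of
    # the interpolation axis so the kernel runs over rows
    yT = _swap_last2(y)                                    # (..., C, R)
    gT = _swap_last2(gap)
    targets = ad.expand_dims(y_sec, -2)                    # (..., 1, S) -> bcast C
    h_b = ad.expand_dims(ad.expand_dims(h, -1), -1)        # (..., 1, 1)
    g_sec = triangular_interp(yT, gT, targets, h_b)        # (..., C, S)
    g_sec = _swap_last2(g_sec)                             # (..., S, C)
    z_col = z.mean(axis=-2)                                # (..., C) span stations
    A = trapezoid_columns(g_sec, ad.expand_dims(z_col, -2))
    A = ad.maximum(A, params.area_floor)
    return y_sec, A


def _swap_last2(a):
    if ad.is_tensor(a):
        axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
        return a.transpose(*axes)
    return np.swapaxes(a, -1, -2)


def min_area(areas, params: FlowParams):
    """(Smooth) minimum of the section areas, never below the floor."""
    if params.tau_min == 0.0:
        am = areas.min(axis=-1) if ad.is_tensor(areas) else np.min(areas, axis=-1)
    else:
        am = ad.softmin(areas, params.tau_min, axis=-1)
    return ad.maximum(am, params.area_floor)


def flow_rate(A_min, params: FlowParams):
    """Bernoulli separation flow rate Q = sqrt(2 P_sub / rho) * A_min."""
    coeff = np.sqrt(2.0 * params.P_sub / params.rho_air)
    return coeff * A_min


def separation_index(areas) -> np.ndarray:
    """Index of the minimum-area section; ties resolve downstream (largest i)."""
    a = ad.asarray(areas)
    rev = a[..., ::-1]
    return a.shape[-1] - 1 - np.argmin(rev, axis=-1)


def pressure_profile(areas, Q, params: FlowParams):
    """Intraglottal pressures: Bernoulli upstream of separation, zero after.

    Returns (pressures, i_sep).  The separation mask is decided on detached
    values (an index is not differentiable); the Bernoulli branch itself
    carries gradients w.r.t. areas and Q.
    """
    i_sep = separation_index(areas)
    S = ad.asarray(areas).shape[-1]
    mask = np.arange(S) <= np.asarray(i_sep)[..., None]    # upstream-or-at
    vel = ad.expand_dims(Q, -1) / areas
    bern = params.P_sub - 0.5 * params.rho_air * ad.square(vel)
    P = ad.where(mask, bern, 0.0 * bern)
    return P, i_sep


def solve_flow(X_grid, params: FlowParams):
    """Convenience evaluation-path wrapper returning a :class:`FlowState`."""
    y_sec, A = section_areas(np.asarray(X_grid, float), params)
    Am = min_area(A, params)
    Q = flow_rate(Am, params)
    P, i_sep = pressure_profile(A, Q, params)
    return FlowState(y_sections=np.asarray(y_sec), areas=np.asarray(A),
                     Q=float(Q), pressures=np.asarray(P), i_sep=int(i_sep))
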