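"""Midline penalty contact.

With only the left fold modeled and left–right symmetry assumed, collision
during glottal closure is represented by a penalty pressure on material that
crosses the midline plane x = 0:

    p_c = k_c1 * dx * (1 + k_c2 * dx**2),   dx = max(0, x - x_mid),

acting along the lateral (-x) direction.  The cubic term stiffens the
penalty for deep penetration so the closed-phase overlap stays a small
fraction of the rest gap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ops import smooth_relu

__all__ = ["ContactParams", "penetration_depth", "contact_pressure"]


@dataclass
class ContactParams:
    """Penalty coefficients.

    The default is a purely linear penalty (k_c2 = 0) at a stiffness that
    bounds penetration to a modest fraction of the vibration amplitude
    (~0.5 mm at ~1.5 mm lateral amplitude for kPa driving pressures).  A
    linear penalty spreads the collision force over the whole closed phase,
    so the modal loading stays band-limited at the ~20 frames/cycle of the
    imaging protocol; the cubic stiffening term, while supported, compresses
    the impulse below that sampling scale."""

    k_c1: float = 5.0e6        # Pa/m
    k_c2: float = 0.0          # 1/m²
    x_mid: float = 0.0         # midline plane location (m)

    def __post_init__(self):
        if self.k_c1 < 0 or self.k_c2 < 0:
            raise ValueError("contact coefficients must be >= 0")


def penetration_depth(x, params: ContactParams | None = None, tau: float = 0.0):
    """Per-point midline penetration dx = max(0, x - x_mid).

    `tau` mollifies the hinge during training; tau = 0 is exact.
    """
    params = params or ContactParams()
    return smooth_relu(x - params.x_mid, tau)


def contact_pressure(dx, params: ContactParams | None = None):
    """Penalty pressure p_c = k_c1 dx (1 + k_c2 dx²), directed along -x."""
    params = params or ContactParams()
    return params.k_c1 * dx * (1.0 + params.k_c2 * dx * dx)
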