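"""Axial (head-less) angle arithmetic.

Cell axes, polarization directions and deformation directions have no sense:
theta and theta + 180 deg are the same direction.  All public quantities are
kept in degrees, reduced to [0, 180).  Averaging and interpolation are done on
the doubled angle (cos 2theta, sin 2theta), which maps axial directions onto
the full circle and removes the wrap-around artifact at 0/180.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reduce_axial",
    "axial_deviation",
    "axial_mean",
    "direction_of",
]


def reduce_axial(angle_deg):
    """Reduce an angle (degrees) to the axial range [0, 180).

    Idempotent; accepts scalars or arrays, negative and non-finite-checked
    input.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("axial angle must be finite")
    out = np.mod(a, 180.0)
    # mod can return 180.0 for tiny negative inputs due to rounding
    out = np.where(out >= 180.0, out - 180.0, out)
    return float(out) if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0 else out


def axial_deviation(a_deg, b_deg):
    """Deviation angle phi between two axial directions, in [0, 90] degrees.

    phi = min(|a-b| mod 180, 180 - |a-b| mod 180); invariant under flipping
    either direction by 180 degrees.
    """
    d = np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float), 180.0)
    phi = np.minimum(d, 180.0 - d)
    return float(phi) if np.ndim(phi) == 0 else phi


def axial_mean(angles_deg, weights=None):
    """Mean axial direction via the doubled-angle vector sum, in [0, 180)."""
    a2 = np.deg2rad(2.0 * np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a2) if weights is None else np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(a2))
    s = np.sum(w * np.sin(a2))
    if np.hypot(c, s) < 1e-9 * max(1.0, np.sum(np.abs(w))):
        raise ValueError("mean axial direction undefined (isotropic input)")
    return reduce_axial(np.rad2deg(0.5 * np.arctan2(s, c)))


def direction_of(dx, dy):
    """Axial direction of a displacement vector, degrees in [0, 180).

    Image convention: x rightward, y downward, angle from the +x axis.
    """
    return reduce_axial(np.rad2deg(np.arctan2(dy, dx)))
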