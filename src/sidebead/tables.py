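"""Periodic bilinear interpolation on (phi, psi) tables.

Used for the one-body rotamer energies v_rot(chi~; phi, psi) and for the
Ramachandran statistical potential.  Tables hold values at midpoint grid
centers on [-pi, pi)^2; interpolation is bilinear with periodic wrap, which
gives a continuous surface with a piecewise-constant (per cell) gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["periodic_bilinear"]


def periodic_bilinear(table: np.ndarray, phi: float, psi: float):
    """Interpolate ``table[..., G1, G2]`` at (phi, psi).

    Returns (value, d/dphi, d/dpsi), each with the leading shape of table.
    """
    table = np.asarray(table, dtype=float)
    G1, G2 = table.shape[-2:]
    d1 = 2 * np.pi / G1
    d2 = 2 * np.pi / G2
    # fractional index relative to cell centers
    u = (phi + np.pi) / d1 - 0.5
    v = (psi + np.pi) / d2 - 0.5
    i0 = int(np.floor(u))
    j0 = int(np.floor(v))
    fu = u - i0
    fv = v - j0
    i0 %= G1
    j0 %= G2
    i1 = (i0 + 1) % G1
    j1 = (j0 + 1) % G2
    f00 = table[..., i0, j0]
    f10 = table[..., i1, j0]
    f01 = table[..., i0, j1]
    f11 = table[..., i1, j1]
    val = ((1 - fu) * (1 - fv) * f00 + fu * (1 - fv) * f10
           + (1 - fu) * fv * f01 + fu * fv * f11)
    dphi = ((1 - fv) * (f10 - f00) + fv * (f11 - f01)) / d1
    dpsi = ((1 - fu) * (f01 - f00) + fu * (f11 - f10)) / d2
    return val, dphi, dpsi
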