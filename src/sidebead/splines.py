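"""Clamped cubic splines over regular knot grids.

The pair potential is built from smooth curves represented by cubic splines
with zero-derivative (clamped) boundary conditions: radial curves live on a
0.5 A knot grid over [0, R_cutoff] and vanish identically at and beyond the
cutoff; angular curves live on a 1/6 grid in cos(theta) over [-1, 1].

Because spline evaluation is linear in the knot values, each curve also
exposes its cardinal basis row B(x) with f(x) = B(x) @ values — the training
gradient with respect to the knot values is exactly that row.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["ClampedSpline", "radial_knots", "angular_knots",
           "basis_matrix", "basis_matrix_derivative"]

RADIAL_SPACING = 0.5          # Angstrom
ANGULAR_SPACING = 1.0 / 6.0   # in cos(theta); the printed 0.167


def radial_knots(r_cutoff: float) -> np.ndarray:
    n = int(round(r_cutoff / RADIAL_SPACING)) + 1
    return np.linspace(0.0, r_cutoff, n)


def angular_knots() -> np.ndarray:
    return np.linspace(-1.0, 1.0, 13)


_BC = ((1, 0.0), (1, 0.0))  # clamped: zero first derivative at both ends


@lru_cache(maxsize=128)
def _cardinal_splines(knots: tuple[float, ...]):
    """One clamped cubic spline per knot, interpolating the unit vectors."""
    x = np.asarray(knots)
    out = []
    for k in range(len(x)):
        e = np.zeros(len(x))
        e[k] = 1.0
        out.append(CubicSpline(x, e, bc_type=_BC))
    return out


def basis_matrix(knots: np.ndarray, x: np.ndarray,
                 zero_tail: bool = False) -> np.ndarray:
    """Cardinal-basis rows: f(x) = basis_matrix(...) @ knot_values.

    With ``zero_tail`` the curve is treated as exactly zero at and beyond the
    last knot (rows there vanish, and the last column is dropped to zero).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kn = tuple(float(v) for v in knots)
    cards = _cardinal_splines(kn)
    xc = np.clip(x, kn[0], kn[-1])
    B = np.stack([c(xc) for c in cards], axis=-1)
    if zero_tail:
        B[..., -1] = 0.0
        B[x >= kn[-1] - 1e-12, :] = 0.0
    return B


def basis_matrix_derivative(knots: np.ndarray, x: np.ndarray,
                            zero_tail: bool = False) -> np.ndarray:
    """Rows of df/dx as a linear function of the knot values."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    kn = tuple(float(v) for v in knots)
    cards = _cardinal_splines(kn)
    inside = (x > kn[0]) & (x < kn[-1])
    xc = np.clip(x, kn[0], kn[-1])
    B = np.stack([c(xc, 1) for c in cards], axis=-1)
    B[~inside, :] = 0.0  # clamped ends: zero slope outside the open interval
    if zero_tail:
        B[..., -1] = 0.0
        B[x >= kn[-1] - 1e-12, :] = 0.0
    return B


class ClampedSpline:
    """Cubic spline through (knots, values) with zero-derivative ends.

    ``zero_tail=True`` additionally forces the value at the last knot to zero
    and returns exactly zero beyond it (the radial cutoff convention).
    """

    def __init__(self, knots, values, zero_tail: bool = False):
        self.knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float).copy()
        if self.knots.ndim != 1 or self.knots.shape != values.shape:
            raise ValueError("knots and values must be matching 1-D arrays")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.zero_tail = bool(zero_tail)
        if self.zero_tail:
            values[-1] = 0.0
        self.values = values
        self._spl = CubicSpline(self.knots, values, bc_type=_BC)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.knots[0], self.knots[-1])
        y = self._spl(xc)
        if self.zero_tail:
            y = np.where(x >= self.knots[-1] - 1e-12, 0.0, y)
        return y

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x > self.knots[0]) & (x < self.knots[-1])
        d = np.where(inside, self._spl(np.clip(x, self.knots[0],
                                               self.knots[-1]), 1), 0.0)
        return d
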