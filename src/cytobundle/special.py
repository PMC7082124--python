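"""Scalar special functions of the bundle force balance.

The steady-state force balance of a treadmilling filament decorated by
transiently bound motors and crosslinks reduces to combinations of four
dimensionless functions:

``S(u)``
    Mean motor-force deficit caused by the motor depletion zone,
    ``S(u) = |u| (1 - exp(-1/|u|))`` where ``u`` is the apparent filament
    velocity (treadmilling minus motor translocation, in units of the
    filament length per motor unbinding time).

``g(y)``
    Mean crosslink-friction deficit caused by the crosslink depletion zone,
    ``g(y) = 2y - (1 + 2y) exp(-1/y)`` with ``y = vt*tauc/L`` the crosslink
    depletion length over the filament length.

``h(y)``
    Companion ratio entering the crosslink contribution to the bundle
    tension; ``h = [4y - 12y^2 + (2 + 8y + 12y^2) e^{-1/y}] / (1 - g(y))``.

``crosslink_moment_factor(y)``
    First position moment of the crosslink force profile,
    ``M(y) = (1/L^2) \\int_0^L xi [1 - (1 + xi/(yL)) e^{-xi/(yL)}] dxi``,
    which depends on ``y`` alone.  Closed form:
    ``M(y) = 1/2 - 3y^2 + (1 + 3y + 3y^2) e^{-1/y}`` and, identically,
    ``M = (1 - g)(2 + h)/4``.

All functions accept scalars or arrays, handle the ``y -> 0`` / ``u -> 0``
continuous extensions exactly, and switch to asymptotic series where the
naive closed forms lose precision to cancellation (y spans many decades in
phase-diagram sweeps).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "S",
    "S_prime",
    "g",
    "one_minus_g",
    "h",
    "crosslink_moment_factor",
]


def _as_nonneg(y, name: str):
    arr = np.asarray(y, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(f"{name} must not be NaN")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0, got {arr}")
    return arr


def _w(x):
    """1 - exp(-1/x) for x > 0, evaluated without cancellation; 1 at x=0."""
    with np.errstate(divide="ignore", over="ignore"):
        return -np.expm1(-1.0 / x)


def S(u):
    """Motor depletion factor |u|(1 - e^(-1/|u|)); S(0) = 0, 0 <= S < 1."""
    arr = np.asarray(u, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("u must not be NaN")
    au = np.abs(arr)
    out = au * _w(au)  # au == 0 gives 0 * 1 = 0, the continuous extension
    return out if out.ndim else float(out)


def S_prime(u):
    """dS/du; odd in u, with the kink limits +-1 at u = 0.

    Returns NaN at exactly u = 0, where S is not differentiable.
    """
    arr = np.asarray(u, dtype=float)
    au = np.abs(arr)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        deriv = _w(au) - np.exp(-1.0 / au) / au
    out = np.where(au == 0.0, np.nan, np.sign(arr) * deriv)
    return out if out.ndim else float(out)


def g(y):
    """Crosslink depletion factor 2y - (1+2y)e^(-1/y); g(0)=0, 0 <= g < 1."""
    arr = _as_nonneg(y, "y")
    # 2y - (1+2y)(1-w) = (1+2y) w - 1 with w = 1 - e^{-1/y}; exact at y=0.
    out = (1.0 + 2.0 * arr) * _w(arr) - 1.0
    out = np.where(np.isinf(arr), 1.0, out)
    return out if out.ndim else float(out)


def one_minus_g(y):
    """1 - g(y), the crosslink-friction retention factor.

    This is also, identically, the denominator of h(y).  For large y the
    direct form cancels catastrophically (1 - g ~ 1/(6y^2)), so an
    asymptotic series in x = 1/y takes over.
    """
    arr = _as_nonneg(y, "y")
    direct = 2.0 - (1.0 + 2.0 * arr) * _w(arr)
    with np.errstate(divide="ignore"):
        x = np.where(arr > 0, 1.0 / arr, np.inf)
    series = x * x * (
        1.0 / 6.0 + x * (-1.0 / 12.0 + x * (1.0 / 40.0 + x * (-1.0 / 180.0 + x / 1008.0)))
    )
    out = np.where(arr > 100.0, series, direct)
    out = np.where(np.isinf(arr), 0.0, out)
    return out if out.ndim else float(out)


def h(y):
    """Crosslink tension companion function, monotone from 0 to 1 on [0, inf)."""
    arr = _as_nonneg(y, "y")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x = np.where(arr > 0, 1.0 / arr, np.inf)
        # Printed form is fine while e^{-1/y} stays subdominant.
        ey = np.exp(np.where(np.isfinite(x), -x, -np.inf))
        num_small = 4.0 * arr - 12.0 * arr**2 + (2.0 + 8.0 * arr + 12.0 * arr**2) * ey
        # Restructured via w = 1 - e^{-1/y} to avoid the 12y^2 cancellation.
        num_mid = 12.0 * arr + 2.0 - (12.0 * arr**2 + 8.0 * arr + 2.0) * _w(arr)
        # Asymptotic series of numerator and denominator, both ~ x^2.
        num_big = 1.0 / 6.0 + x * (-0.1 + x * (1.0 / 30.0 + x * (-1.0 / 126.0 + x / 672.0)))
        den_big = 1.0 / 6.0 + x * (
            -1.0 / 12.0 + x * (1.0 / 40.0 + x * (-1.0 / 180.0 + x / 1008.0))
        )
        num = np.where(arr <= 0.5, num_small, num_mid)
        den = one_minus_g(arr)
        ratio = np.where(arr > 0, num / np.where(den > 0, den, 1.0), 0.0)
        ratio_big = num_big / den_big
    out = np.where(arr > 100.0, ratio_big, ratio)
    out = np.where(arr == 0.0, 0.0, out)
    out = np.where(np.isinf(arr), 1.0, out)
    return out if out.ndim else float(out)


def crosslink_moment_factor(y):
    """First moment M(y) of the crosslink force profile over the filament.

    M(y) = 1/2 - 3y^2 + (1 + 3y + 3y^2) e^{-1/y}; limits M(0) = 1/2 (uniform
    crosslink force) and M(inf) = 0 (fully depleted crosslinks).  Computed in
    a cancellation-free restructuring for y <= 10 and by the asymptotic
    series M ~ x^2/8 - x^3/15 + ... (x = 1/y) above.
    """
    arr = _as_nonneg(y, "y")
    # 1/2 - 3y^2 + (1+3y+3y^2)(1 - w) = 3/2 + 3y - (1+3y+3y^2) w
    direct = 1.5 + 3.0 * arr - (1.0 + 3.0 * arr + 3.0 * arr**2) * _w(arr)
    with np.errstate(divide="ignore"):
        x = np.where(arr > 0, 1.0 / arr, np.inf)
    series = x * x * (
        0.125
        + x
        * (
            -1.0 / 15.0
            + x
            * (
                1.0 / 48.0
                + x * (-1.0 / 210.0 + x * (1.0 / 1152.0 + x * (-1.0 / 7560.0 + x / 57600.0)))
            )
        )
    )
    out = np.where(arr > 10.0, series, direct)
    out = np.where(np.isinf(arr), 0.0, out)
    return out if out.ndim else float(out)
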