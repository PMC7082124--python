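"""Filament tension profiles and the bundle-averaged tension.

A filament carries a force per unit length ``f(xi) = z*[fm(xi) + fc(xi)]``
and a tension ``T(xi) = -int_0^xi f`` that vanishes at both ends once the
motor velocity is at a steady state.  Averaging over the uniformly
distributed intersection coordinate of the many filaments crossing a bundle
section gives the bundle tension ``T_bundle = rho_f * int_0^L T(xi) dxi``;
in units of ``z*rho_f*L^2*fm0`` (and after one integration by parts) this is
the first position moment of the force density,

    T_t = (1/L_t^2) int_0^{L_t} xi * [fm(xi) + fc(xi)] dxi,

which is the authoritative definition used throughout.  The motor part has
the closed form (u = apparent velocity)

    Tm_t = 1/2 - u^2 + u(1+u) e^{-1/u}          (u > 0)
    Tm_t = 1/2 - u^2 e^{1/u} + u(1+u)           (u < 0)

and the crosslink part is ``Tc_t = -vm_t * M(y)`` with the moment factor
``M`` of :mod:`cytobundle.special` and the steady-state velocity
``vm_t = (1 - S(u))/(1 - g(y))``.  ``T_t > 0`` means a tense (contractile)
bundle, ``T_t < 0`` a compressed (extensile) one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .params import DimensionlessParams
from .profiles import crosslink_force_density, motor_force_density, net_force
from .special import S, crosslink_moment_factor, h, one_minus_g

__all__ = [
    "TensionResult",
    "motor_tension",
    "steady_motor_velocity",
    "crosslink_tension",
    "crosslink_tension_h_form",
    "bundle_tension",
    "tension_from_moment",
    "tension_profile",
    "dimensional_tension",
    "tension_map",
]

#: |T_t| below this is classified neutral
_NEUTRAL_TOL = 1e-9
#: |net_force| above this fails the steady-state precondition
_STEADY_TOL = 1e-6


def motor_tension(u):
    """Motor contribution Tm_t as a function of the apparent velocity alone.

    Continuous across u = 0 (both branches -> 1/2) and -> 0 as |u| -> inf;
    an asymptotic series takes over for |u| > 100 where the closed form
    cancels.
    """
    arr = np.asarray(u, dtype=float)
    au = np.abs(arr)
    with np.errstate(divide="ignore", over="ignore", under="ignore", invalid="ignore"):
        e = np.exp(-1.0 / np.where(au > 0, au, 1.0))
        e = np.where(au > 0, e, 0.0)
        pos = 0.5 - arr**2 + arr * (1.0 + arr) * e
        neg = 0.5 - arr**2 * e + arr * (1.0 + arr)
        x = np.where(au > 0, 1.0 / au, np.inf)
        series_pos = x / 3.0 - x * x / 8.0
        series_neg = x / 6.0 - x * x / 24.0
    out = np.where(arr >= 0, pos, neg)
    out = np.where(arr == 0.0, 0.5, out)
    big = au > 100.0
    out = np.where(big & (arr > 0), series_pos, out)
    out = np.where(big & (arr < 0), series_neg, out)
    return out if out.ndim else float(out)


def steady_motor_velocity(u, y):
    """vm_t = (1 - S(u)) / (1 - g(y)), the force-balance velocity at root u."""
    return (1.0 - S(u)) / one_minus_g(y)


def crosslink_tension(u, y):
    """Crosslink contribution Tc_t = -vm_t * M(y) at a steady state."""
    return -steady_motor_velocity(u, y) * crosslink_moment_factor(y)


def crosslink_tension_h_form(u, y):
    """Equivalent closed form Tc_t = [S(u) - 1] * (2 + h(y)) / 4.

    Follows from the identity M(y) = (1 - g(y)) (2 + h(y)) / 4 combined with
    the steady-state velocity; kept as an independent cross-check of
    :func:`crosslink_tension`, which is the computation path.
    """
    return (S(u) - 1.0) * (2.0 + h(y)) / 4.0


@dataclass
class TensionResult:
    """Bundle tension decomposition at one steady state."""

    u: float
    Tm_t: float
    Tc_t: float
    T_t: float
    classification: str
    vm_t: float
    y: float


def bundle_tension(u: float, p: DimensionlessParams, *, check: bool = True) -> TensionResult:
    """Dimensionless bundle tension at the force-balance root ``u``.

    Raises if ``u`` is not a steady state of ``p`` (unless ``check=False``,
    e.g. for exploratory maps over off-balance states).
    """
    y = p.y
    vm_t = steady_motor_velocity(u, y)
    if check:
        resid = net_force(p.vt_t - u * p.L_t, p)
        if abs(resid) > _STEADY_TOL * max(1.0, p.L_t):
            raise ValueError(
                f"u={u} is not a steady state (net force residual {resid:.3e})"
            )
    Tm = float(motor_tension(u))
    Tc = float(crosslink_tension(u, y))
    total = Tm + Tc
    if total > _NEUTRAL_TOL:
        cls = "contractile"
    elif total < -_NEUTRAL_TOL:
        cls = "extensile"
    else:
        cls = "neutral"
    return TensionResult(
        u=float(u), Tm_t=Tm, Tc_t=Tc, T_t=total, classification=cls, vm_t=float(vm_t), y=y
    )


def tension_from_moment(vm_t: float, p: DimensionlessParams) -> float:
    """Adaptive quadrature of the defining moment (1/L^2) int xi*[fm+fc] dxi.

    Independent of the closed forms; used to validate them.
    """

    def integrand(xi):
        return xi * (
            motor_force_density(xi, vm_t, p) + crosslink_force_density(xi, vm_t, p)
        )

    val, _ = quad(integrand, 0.0, p.L_t, limit=200, epsabs=1e-12, epsrel=1e-12)
    return val / p.L_t**2


def tension_profile(xi, vm_t: float, p: DimensionlessParams):
    """Tension T(xi) = -int_0^xi [fm + fc] along the filament (z factored out).

    Uses the closed-form antiderivatives of the force densities.  Requires
    ``vm_t`` to be a steady state so that T vanishes at both ends.
    """
    if abs(net_force(vm_t, p)) > _STEADY_TOL * max(1.0, p.L_t):
        raise ValueError("vm_t is not a steady state; tension ends would not vanish")
    arr = np.asarray(xi, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > p.L_t * (1 + 1e-12)):
        raise ValueError(f"xi must lie in [0, {p.L_t}]")
    arr = np.clip(arr, 0.0, p.L_t)
    d = p.vt_t - vm_t
    with np.errstate(under="ignore"):
        if d > 0:
            Im = arr - d * (1.0 - np.exp(-arr / d))
        elif d < 0:
            dd = -d
            Im = arr - dd * (np.exp(-(p.L_t - arr) / dd) - np.exp(-p.L_t / dd))
        else:
            Im = arr.copy()
        c = p.vt_t * p.tauc_t
        if c > 0:
            Ic = -vm_t * (arr - 2.0 * c + (2.0 * c + arr) * np.exp(-arr / c))
        else:
            Ic = -vm_t * arr
    out = -(Im + Ic)
    return out if out.ndim else float(out)


def dimensional_tension(T_t: float, z: int, rho_f: float, L: float, fm0: float) -> float:
    """Convert a dimensionless bundle tension to Newtons: T_t*z*rho_f*L^2*fm0."""
    for name, v in (("z", z), ("rho_f", rho_f), ("L", L), ("fm0", fm0)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return T_t * z * rho_f * L**2 * fm0


def tension_map(u_grid, y_grid):
    """Bundle tension T_t(u, y) on a grid, plus its zero contour.

    Evaluates the steady-state tension as a function of the apparent
    velocity and the crosslink depletion ratio only.  Returns ``(T, pts)``
    where ``T[i, j]`` corresponds to ``(y_grid[i], u_grid[j])`` and ``pts``
    is an (n, 2) array of (u, y) points on the contraction/extension
    boundary obtained by linear interpolation of sign changes along u.
    """
    u = np.asarray(u_grid, dtype=float)
    y = np.asarray(y_grid, dtype=float)
    T = motor_tension(u)[None, :] + (
        -steady_motor_velocity(u[None, :], y[:, None]) * crosslink_moment_factor(y)[:, None]
    )
    pts = []
    for i, yi in enumerate(y):
        row = T[i]
        flips = np.nonzero(np.diff(np.sign(row)) != 0)[0]
        for j in flips:
            frac = row[j] / (row[j] - row[j + 1])
            pts.append((u[j] + frac * (u[j + 1] - u[j]), yi))
    return T, np.asarray(pts).reshape(-1, 2)
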