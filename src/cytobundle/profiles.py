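"""Steady-state force-density profiles along a filament.

Positions ``xi`` are measured from the filament plus end in units of
``vm0*tau_m``; force densities are in units of ``fm0``.  The motor profile
is depleted over a length ``|vt_t - vm_t|`` next to the end where new
filament/overlap is created; the crosslink profile is depleted over
``vt_t*tauc_t`` next to the plus end.  The crosslink prefactor
``2*kc*rho_c0*tau_c*vm`` equals ``vm_t*fm0`` by the definition of ``vm0``,
so the whole computation is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import DimensionlessParams
from .special import S, one_minus_g

__all__ = [
    "ForceProfile",
    "motor_force_density",
    "crosslink_force_density",
    "net_force",
    "net_force_derivative",
    "force_profile",
]


def _check_xi(xi, L_t):
    arr = np.asarray(xi, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > L_t * (1 + 1e-12)):
        raise ValueError(f"xi must lie in [0, {L_t}]")
    return np.clip(arr, 0.0, L_t)


def motor_force_density(xi, vm_t: float, p: DimensionlessParams):
    """Motor force density fm(xi)/fm0 for motor velocity ``vm_t``.

    Piecewise by the sign of vt_t - vm_t: depletion at the plus end when
    treadmilling outruns the motors, at the minus end otherwise; exactly 1
    (uniform) when vt_t == vm_t.
    """
    arr = _check_xi(xi, p.L_t)
    d = p.vt_t - vm_t
    with np.errstate(under="ignore"):
        if d > 0:
            out = -np.expm1(-arr / d)
        elif d < 0:
            out = -np.expm1(-(p.L_t - arr) / (-d))
        else:
            out = np.ones_like(arr)
    return out if out.ndim else float(out)


def crosslink_force_density(xi, vm_t: float, p: DimensionlessParams):
    """Crosslink force density fc(xi)/fm0 = -vm_t [1 - (1 + xi/c) e^(-xi/c)].

    ``c = vt_t*tauc_t`` is the crosslink depletion length.  At vt_t = 0 the
    crosslink coverage is uniform and the density is -vm_t for xi > 0 (0 at
    the plus end itself, as freshly polymerized tip carries no crosslinks).
    """
    arr = _check_xi(xi, p.L_t)
    c = p.vt_t * p.tauc_t
    with np.errstate(under="ignore"):
        if c > 0:
            out = -vm_t * (1.0 - (1.0 + arr / c) * np.exp(-arr / c))
        else:
            out = np.where(arr > 0, -vm_t, 0.0)
    return out if out.ndim else float(out)


def net_force(vm_t: float, p: DimensionlessParams) -> float:
    """Total dimensionless force F(vm_t) = int_0^L [fm + fc] dxi on a filament.

    Closed form: ``L_t*[1 - S(u)] - vm_t*L_t*[1 - g(y)]`` with
    ``u = (vt_t - vm_t)/L_t`` and ``y = vt_t*tauc_t/L_t``.  Steady-state
    motor velocities are the zeros of this function.
    """
    u = (p.vt_t - vm_t) / p.L_t
    return p.L_t * (1.0 - S(u)) - vm_t * p.L_t * one_minus_g(p.y)


def net_force_derivative(vm_t: float, p: DimensionlessParams) -> float:
    """Analytic dF/dvm_t = S'(u) - L_t*[1 - g(y)]; NaN at the u = 0 kink."""
    from .special import S_prime

    u = (p.vt_t - vm_t) / p.L_t
    return S_prime(u) - p.L_t * one_minus_g(p.y)


@dataclass
class ForceProfile:
    """Sampled force-density profiles for one motor velocity."""

    xi: np.ndarray
    fm: np.ndarray
    fc: np.ndarray
    vm_t: float
    params: DimensionlessParams

    @property
    def total(self) -> np.ndarray:
        return self.fm + self.fc

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"xi": self.xi, "fm": self.fm, "fc": self.fc, "total": self.total}
        )

    def to_csv(self, path) -> None:
        """Tidy CSV with a comment header recording (vt_t, tauc_t, L_t, vm_t)."""
        p = self.params
        header = (
            f"# vt_t={p.vt_t!r} tauc_t={p.tauc_t!r} L_t={p.L_t!r} vm_t={self.vm_t!r}\n"
        )
        path = Path(path)
        with path.open("w") as fh:
            fh.write(header)
            self.to_dataframe().to_csv(fh, index=False)


def force_profile(vm_t: float, p: DimensionlessParams, n: int = 2048) -> ForceProfile:
    """Evaluate both force densities on a uniform grid of ``n`` points."""
    xi = np.linspace(0.0, p.L_t, n)
    return ForceProfile(
        xi=xi,
        fm=motor_force_density(xi, vm_t, p),
        fc=crosslink_force_density(xi, vm_t, p),
        vm_t=vm_t,
        params=p,
    )
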