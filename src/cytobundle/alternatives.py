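"""Competing contraction mechanisms: filament buckling and motor end-dwelling.

Two alternative explanations of bundle contractility are implemented for
quantitative comparison with the self-organization tension:

* **Buckling** (flexible, actin-like filaments): compressive segments
  between a motor and a crosslink buckle when the motor/crosslink spacing
  ``l0`` lies inside a window ``l0- < l0 < l0+``; a buckled bundle then
  pulls with the minifilament stall force ``Fs``, and generates nothing
  outside the window.  The bounds are evaluated exactly as the source model
  states them on SI magnitudes:

      l0- = (kB*T * lp / (Fs * sqrt(L)))^(2/3)
      l0+ = (L * v * tau_m * lp)^(2/5)

  (the 2/5-power expression is dimensionally an empirical boundary; the
  exponent is configurable).

* **End-dwelling** (microtubule-like systems): motors reaching the plus end
  pause there for a mean time tau_m while all other attachment dynamics is
  instantaneous.  The force balance then gives, for vt_t < 1 and L_t > 2,

      vm_t = (L_t - 2*vt_t) / (L_t - 2),
      T_dwell_t = -(1 - vt_t) / (2*(L_t - 2)),

  always extensile; fast treadmilling (vt_t >= 1) removes dwelling
  entirely (vm_t = 1, zero tension), and short filaments (L_t < 2) provide
  too little crosslink friction to arrest the dwelling positive feedback,
  so no steady state exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DimensionlessParams

__all__ = [
    "BucklingParams",
    "DwellingResult",
    "buckling_bounds",
    "buckling_tension",
    "buckling_comparison_map",
    "dwelling_steady_state",
    "dwelling_net_force",
    "dwelling_relaxation",
    "dwelling_threshold_length",
    "dwelling_comparison_map",
]


@dataclass(frozen=True)
class BucklingParams:
    """Inputs of the buckling-window estimate (SI units).

    ``Fs`` and ``tau_m`` are computed, not free: the minifilament stall
    force is ``n * stall_per_head`` and the detachment time grows with the
    head count as ``tau_m_base * tau_m_rate**(-n)`` (the chance that all
    heads release simultaneously shrinks geometrically with n).
    """

    n: int
    l0: float
    lp: float = 10e-6
    L: float = 5e-6
    v: float = 200e-9
    kBT: float = 4.1e-21
    stall_per_head: float = 0.1e-12
    tau_m_base: float = 3e-3
    tau_m_rate: float = 0.96
    upper_bound_exponent: float = 2.0 / 5.0

    def __post_init__(self):
        for name in ("l0", "lp", "L", "v", "kBT", "stall_per_head", "tau_m_base"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.tau_m_rate < 1:
            raise ValueError("tau_m_rate must lie in (0, 1)")
        if not self.n >= 1:
            raise ValueError("n must be >= 1")

    @property
    def Fs(self) -> float:
        """Minifilament stall force n * 0.1 pN [N]."""
        return self.n * self.stall_per_head

    @property
    def tau_m(self) -> float:
        """Motor detachment time, increasing with head count [s]."""
        return self.tau_m_base * self.tau_m_rate ** (-self.n)


def buckling_bounds(bp: BucklingParams) -> tuple[float, float]:
    """(l0-, l0+): spacing window inside which buckling is possible.

    No ordering is guaranteed; l0- >= l0+ means an empty window.
    """
    l0_minus = (bp.kBT * bp.lp / (bp.Fs * np.sqrt(bp.L))) ** (2.0 / 3.0)
    l0_plus = (bp.L * bp.v * bp.tau_m * bp.lp) ** bp.upper_bound_exponent
    return float(l0_minus), float(l0_plus)


def buckling_tension(bp: BucklingParams) -> float:
    """Per-filament buckling tension: Fs inside the window, 0 outside [N]."""
    lo, hi = buckling_bounds(bp)
    return bp.Fs if lo < bp.l0 < hi else 0.0


def _self_organization_tension_per_filament(
    n: int,
    l0: float,
    *,
    vt: float,
    vm0: float,
    tau_c: float,
    z: int,
    L: float,
    bp_template: BucklingParams,
) -> float:
    """Dimensional self-organization tension extrapolated to one filament.

    The motor force density is the minifilament stall force per spacing,
    ``fm0 = Fs/l0``; tau_m follows the head count.  With one filament per
    cross-section (rho_f*L = 1) the tension is ``z*L*fm0*T_t``.  Where two
    stable branches coexist the branch of largest |T_t| is reported.
    """
    from .tension import bundle_tension
    from .velocity import ab_coefficients, solve_velocity

    bp = BucklingParams(
        n=n, l0=l0, lp=bp_template.lp, L=bp_template.L, v=bp_template.v,
        kBT=bp_template.kBT, stall_per_head=bp_template.stall_per_head,
        tau_m_base=bp_template.tau_m_base, tau_m_rate=bp_template.tau_m_rate,
    )
    fm0 = bp.Fs / l0
    tau_m = bp.tau_m
    p = DimensionlessParams(vt_t=vt / vm0, tauc_t=tau_c / tau_m, L_t=L / (vm0 * tau_m))
    sol = solve_velocity(ab_coefficients(p), p)
    tensions = [
        bundle_tension(u, p).T_t
        for u, s in zip(sol.roots, sol.stability)
        if s == "stable"
    ]
    T_t = max(tensions, key=abs)
    return z * L * fm0 * T_t


def buckling_comparison_map(
    n_grid,
    l0_grid,
    *,
    vt: float = 100e-9,
    vm0: float = 50e-9,
    tau_c: float = 1.0,
    z: int = 3,
    L: float = 5e-6,
    bp_template: BucklingParams | None = None,
) -> pd.DataFrame:
    """Tidy grid of |T_self| vs T_buckling over (n, l0), per filament.

    Defaults follow the experimentally motivated parameter set used for the
    dashed-line scan (vt = 100 nm/s, vm0 = 50 nm/s, tau_c = 1 s, z = 3) with
    the buckling model's 5 um filaments.
    """
    if bp_template is None:
        bp_template = BucklingParams(n=1, l0=1e-7, L=L)
    rows = []
    for n in np.asarray(n_grid):
        n = int(n)
        bounds_bp = BucklingParams(
            n=n, l0=1e-7, lp=bp_template.lp, L=bp_template.L, v=bp_template.v,
            kBT=bp_template.kBT, stall_per_head=bp_template.stall_per_head,
            tau_m_base=bp_template.tau_m_base, tau_m_rate=bp_template.tau_m_rate,
        )
        lo, hi = buckling_bounds(bounds_bp)
        for l0 in np.asarray(l0_grid, dtype=float):
            T_self = _self_organization_tension_per_filament(
                n, l0, vt=vt, vm0=vm0, tau_c=tau_c, z=z, L=bp_template.L,
                bp_template=bp_template,
            )
            T_buck = bounds_bp.Fs if lo < l0 < hi else 0.0
            rows.append(
                {
                    "n": n, "l0": l0, "l0_minus": lo, "l0_plus": hi,
                    "T_self": T_self, "T_buckling": T_buck,
                    "self_dominates": abs(T_self) > T_buck,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DwellingResult:
    """Steady state of the end-dwelling model."""

    vm_t: float
    T_dwell_t: float
    status: str  # steady | no_steady_state | no_dwelling


def dwelling_steady_state(vt_t: float, L_t: float) -> DwellingResult:
    """Closed-form steady state of the end-dwelling force balance."""
    if vt_t < 0 or not L_t > 0:
        raise ValueError("need vt_t >= 0 and L_t > 0")
    if vt_t >= 1.0:
        return DwellingResult(vm_t=1.0, T_dwell_t=0.0, status="no_dwelling")
    if L_t > 2.0:
        vm = (L_t - 2.0 * vt_t) / (L_t - 2.0)
        assert vm > vt_t, "dwelling requires motors to outrun treadmilling"
        return DwellingResult(
            vm_t=vm, T_dwell_t=-(1.0 - vt_t) / (2.0 * (L_t - 2.0)), status="steady"
        )
    return DwellingResult(vm_t=float("nan"), T_dwell_t=float("nan"), status="no_steady_state")


def dwelling_net_force(vm_t: float, vt_t: float, L_t: float) -> float:
    """Net dimensionless force (2 - L_t)*vm_t + L_t - 2*vt_t of the dwelling model.

    Integral of the dwelling force densities: uniform motors contribute
    L_t, the end-dwelling population 2*(vm_t - vt_t) (on-filament plus
    neighbor dwellers), and the undepleted crosslink friction -vm_t*L_t.
    """
    return (2.0 - L_t) * vm_t + L_t - 2.0 * vt_t


def dwelling_relaxation(
    vt_t: float,
    L_t: float,
    *,
    vm_init: float = 1.0,
    mobility: float = 1.0,
    max_time: float = 2e4,
    guard: float = 1e3,
    tol: float = 1e-9,
) -> tuple[str, float]:
    """Relax dvm/dt = mobility*F toward a dwelling steady state.

    Returns ('steady', vm) on convergence, ('no_steady_state', vm) when the
    velocity runs away past ``guard`` — the positive feedback of motor
    accumulation at the plus end that short filaments cannot arrest.
    """
    vm = vm_init
    rate = max(abs(2.0 - L_t) * mobility, 1e-3)
    dt = 0.1 / rate
    t = 0.0
    while t < max_time:
        F = dwelling_net_force(vm, vt_t, L_t)
        if abs(F) < tol * (1.0 + abs(vm)):
            return "steady", vm
        vm += mobility * F * dt
        if abs(vm) > guard:
            return "no_steady_state", vm
        t += dt
    return ("steady", vm) if abs(dwelling_net_force(vm, vt_t, L_t)) < 1e-6 else (
        "no_steady_state",
        vm,
    )


def dwelling_threshold_length(
    vt_t: float = 0.5, lo: float = 1.2, hi: float = 3.0, tol: float = 1e-3
) -> float:
    """Critical L_t separating steady from runaway dwelling dynamics, by bisection.

    Uses only the relaxation dynamics (no closed-form case split), so the
    threshold is measured, not assumed.
    """
    if dwelling_relaxation(vt_t, lo)[0] != "no_steady_state":
        raise ValueError("lo must start in the runaway regime")
    if dwelling_relaxation(vt_t, hi)[0] != "steady":
        raise ValueError("hi must start in the steady regime")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if dwelling_relaxation(vt_t, mid)[0] == "steady":
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def dwelling_comparison_map(vt_grid, L_grid, tauc_t: float) -> pd.DataFrame:
    """Tidy grid of |T_self| vs |T_dwell| over (vt_t, L_t) at fixed tauc_t.

    Cells where the dwelling model has no steady state are labelled; where
    two self-organization branches are stable the larger |T_t| is used.
    """
    from .tension import bundle_tension
    from .velocity import ab_coefficients, solve_velocity

    rows = []
    for vt_t in np.asarray(vt_grid, dtype=float):
        for L_t in np.asarray(L_grid, dtype=float):
            p = DimensionlessParams(vt_t=vt_t, tauc_t=tauc_t, L_t=L_t)
            sol = solve_velocity(ab_coefficients(p), p)
            T_self = max(
                (
                    bundle_tension(u, p).T_t
                    for u, s in zip(sol.roots, sol.stability)
                    if s == "stable"
                ),
                key=abs,
            )
            dw = dwelling_steady_state(vt_t, L_t)
            dominates = (
                "self"
                if dw.status != "steady" or abs(T_self) > abs(dw.T_dwell_t)
                else "dwelling"
            )
            rows.append(
                {
                    "vt_t": vt_t, "L_t": L_t, "tauc_t": tauc_t,
                    "T_self": T_self, "T_dwell": dw.T_dwell_t,
                    "dwelling_status": dw.status, "dominant": dominates,
                }
            )
    return pd.DataFrame(rows)
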