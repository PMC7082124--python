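"""Velocity selection: roots of the force balance, stability, regimes.

Demanding that the net force on a filament vanish yields the transcendental
equation

    S(u) = (1 - a) + b*u,      u = (vt_t - vm_t)/L_t,

with ``a = vt_t*[1 - g(y)]``, ``b = L_t*[1 - g(y)]`` and ``y =
vt_t*tauc_t/L_t``.  Because S saturates below 1 the equation has either one
root or three; in the three-root (coexistence) regime the middle root — the
smaller of the two u > 0 roots — is unstable, so two stable steady states of
opposite apparent-velocity sign coexist and parameter sweeps through the
window exhibit hysteresis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import DimensionlessParams
from .special import S, S_prime, g, one_minus_g

__all__ = [
    "ABCoefficients",
    "Regime",
    "VelocitySolution",
    "BranchPoint",
    "ab_coefficients",
    "force_balance_residual",
    "force_derivative",
    "solve_velocity",
    "stability",
    "classify_regime",
    "coexistence_onset",
    "branch_continuation",
]

#: two roots closer than this are considered one tangency (marginal) root
_MERGE_TOL = 1e-8
#: |dF/dvm| below this is flagged marginal
_MARGINAL_TOL = 1e-10


class Regime(str, enum.Enum):
    U_NEGATIVE = "U_NEGATIVE"
    U_POSITIVE = "U_POSITIVE"
    COEXISTENCE = "COEXISTENCE"


@dataclass(frozen=True)
class ABCoefficients:
    """Constants of the velocity-selection line (1 - a) + b*u."""

    a: float
    b: float
    y: float

    def __post_init__(self):
        if self.a < 0 or self.b <= 0:
            raise ValueError(f"need a >= 0 and b > 0, got a={self.a}, b={self.b}")


def ab_coefficients(p: DimensionlessParams) -> ABCoefficients:
    """a = vt_t*(1 - g(y)), b = L_t*(1 - g(y)); a -> vt_t, b -> L_t as y -> 0."""
    retention = one_minus_g(p.y)
    return ABCoefficients(a=p.vt_t * retention, b=p.L_t * retention, y=p.y)


def force_balance_residual(u, ab: ABCoefficients):
    """S(u) - (1 - a) - b*u; zero at a selected steady state."""
    return S(u) - (1.0 - ab.a) - ab.b * np.asarray(u, dtype=float)


def force_derivative(u: float, ab: ABCoefficients) -> float:
    """dF/dvm_t at apparent velocity u, equal to S'(u) - b (F in fm0*vm0*tau_m units)."""
    return S_prime(u) - ab.b


@dataclass
class VelocitySolution:
    """All real roots u of the force balance with stability labels."""

    roots: np.ndarray
    stability: list[str]
    regime: Regime
    vm_roots: np.ndarray
    ab: ABCoefficients
    marginal: bool = False


def solve_velocity(
    ab: ABCoefficients,
    p: DimensionlessParams | None = None,
    *,
    n_grid: int = 20001,
    u_max: float = 50.0,
) -> VelocitySolution:
    """Find every real root of S(u) = (1 - a) + b*u and classify it.

    Roots are bracketed by sign changes on a dense grid and polished by
    Brent's method.  Since 0 <= S < 1, all roots satisfy
    (a - 1)/b <= u <= a/b; the search window is that interval padded by one
    unit and clipped to ``u_max`` (expanded once on failure).  ``vm_roots``
    requires ``p`` only for the u -> vm_t conversion; with ``p`` omitted the
    conversion uses L_t = b/(1 - g(y)) and vt_t = a*L_t/b, which is exact.
    """
    if p is not None:
        L_t, vt_t = p.L_t, p.vt_t
    else:
        retention = one_minus_g(ab.y)
        L_t = ab.b / retention
        vt_t = ab.a / retention

    lo = (ab.a - 1.0) / ab.b - 1.0
    hi = ab.a / ab.b + 1.0
    for attempt in range(2):
        cap = u_max * (10.0**attempt)
        grid = np.linspace(max(lo, -cap), min(hi, cap), n_grid)
        res = force_balance_residual(grid, ab)
        sign = np.sign(res)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        roots = []
        for i in idx:
            if res[i] == 0.0:
                roots.append(grid[i])
                continue
            roots.append(
                brentq(lambda x: force_balance_residual(x, ab), grid[i], grid[i + 1], xtol=1e-14)
            )
        if res[-1] == 0.0:
            roots.append(grid[-1])
        # The kink of S at u=0 can carry a tangential root missed by sign changes.
        if abs(1.0 - ab.a) < 1e-12 and not any(abs(r) < _MERGE_TOL for r in roots):
            roots.append(0.0)
        if roots:
            break
    else:  # pragma: no cover - S saturates, so a root always exists in range
        raise RuntimeError("no root found; search range exhausted")

    roots = np.sort(np.asarray(roots))
    merged, marginal = [], False
    for r in roots:
        if merged and abs(r - merged[-1]) < _MERGE_TOL:
            marginal = True
            continue
        merged.append(float(r))
    roots = np.asarray(merged)

    labels = [stability(r, ab) for r in roots]
    if len(roots) >= 3 or (len(roots) == 2):
        regime = Regime.COEXISTENCE
        marginal = marginal or len(roots) == 2
    else:
        regime = Regime.U_NEGATIVE if roots[0] < 0 else Regime.U_POSITIVE
    vm_roots = vt_t - roots * L_t
    return VelocitySolution(
        roots=roots,
        stability=labels,
        regime=regime,
        vm_roots=vm_roots,
        ab=ab,
        marginal=marginal,
    )


def stability(u: float, ab: ABCoefficients) -> str:
    """'stable' iff dF/dvm_t = S'(u) - b < 0 at the root, 'unstable' if > 0.

    Within ``1e-10`` of zero the root is a tangency and labelled 'marginal'.
    At exactly u = 0 (kink of S) the label follows the more unstable of the
    two one-sided derivatives.
    """
    if u == 0.0:
        deriv = max(1.0 - ab.b, -1.0 - ab.b)
    else:
        deriv = force_derivative(u, ab)
    if abs(deriv) < _MARGINAL_TOL:
        return "marginal"
    return "stable" if deriv < 0 else "unstable"


def classify_regime(ab: ABCoefficients) -> Regime:
    """Solve and report which of the three dynamical regimes ``ab`` is in."""
    return solve_velocity(ab).regime


def coexistence_onset(b: float) -> float:
    """Lower boundary a_c(b) of the coexistence region at fixed b < 1.

    At the boundary the two u > 0 roots merge: S(u) = (1-a) + b u and
    S'(u) = b simultaneously.  Returns NaN for b >= 1, where the slope of S
    near u = 0+ (-> 1) never exceeds b and the u-sign change is continuous
    (second order); the upper boundary is a = 1 (where the u < 0 root dies).
    """
    if b >= 1.0:
        return float("nan")
    u_t = brentq(lambda x: S_prime(x) - b, 1e-12, 1e12, xtol=1e-14)
    return 1.0 - S(u_t) + b * u_t


@dataclass
class BranchPoint:
    """One step of a branch continuation."""

    u: float
    vm_t: float
    stable: str
    regime: Regime
    jumped: bool
    params: DimensionlessParams


def branch_continuation(
    path: list[DimensionlessParams],
    start_branch: str | float = "auto",
    *,
    jump_factor: float = 10.0,
) -> list[BranchPoint]:
    """Follow a stable root along a 1-parameter family of parameter sets.

    At each step the stable root nearest (in u) to the previously selected
    one is followed; a first-order jump is recorded when the followed branch
    disappears (the nearest stable root is farther than ``jump_factor``
    times the recent step-to-step variation).  ``start_branch`` is 'auto'
    (single stable root required at the start), 'lower'/'upper' (smallest /
    largest stable u), or a float taken as the initial u guess.
    """
    out: list[BranchPoint] = []
    u_prev: float | None = None
    recent_steps: list[float] = []
    for p in path:
        ab = ab_coefficients(p)
        sol = solve_velocity(ab, p)
        stable_u = [r for r, s in zip(sol.roots, sol.stability) if s == "stable"]
        if not stable_u:
            raise RuntimeError(f"no stable root at {p}")
        if u_prev is None:
            if isinstance(start_branch, (int, float)):
                u_sel = min(stable_u, key=lambda r: abs(r - start_branch))
            elif start_branch == "lower":
                u_sel = min(stable_u)
            elif start_branch == "upper":
                u_sel = max(stable_u)
            else:
                if len(stable_u) > 1:
                    raise ValueError(
                        "start of path is in a coexistence window; pass "
                        "start_branch='lower'/'upper' or an initial u"
                    )
                u_sel = stable_u[0]
            jumped = False
        else:
            dists = sorted(abs(r - u_prev) for r in stable_u)
            if len(dists) > 1 and dists[1] - dists[0] < 1e-12:
                raise RuntimeError(
                    "nearest-root tie during continuation; refine the path step"
                )
            u_sel = min(stable_u, key=lambda r: abs(r - u_prev))
            typical = max(recent_steps[-5:], default=0.0)
            # absolute floor keeps smooth early steps from counting as jumps
            jumped = abs(u_sel - u_prev) > max(jump_factor * typical, 0.1)
            if not jumped:
                recent_steps.append(abs(u_sel - u_prev))
        u_prev = u_sel
        out.append(
            BranchPoint(
                u=float(u_sel),
                vm_t=float(p.vt_t - u_sel * p.L_t),
                stable="stable",
                regime=sol.regime,
                jumped=jumped,
                params=p,
            )
        )
    return out
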