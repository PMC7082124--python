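"""Parameter sweeps: regime maps, contractility maps, and line scans.

The (a, b) plane splits into three regions: a single u < 0 root (motors
outrun treadmilling), a single u > 0 root, and a coexistence wedge with two
stable roots of opposite sign.  The boundaries are a = 1 (where the u < 0
root disappears) and the tangency curve a_c(b) of the line (1 - a) + b*u
with S(u) on u > 0, which exists only for b < 1 — for b >= 1 the u-sign
change is continuous (second order).  In the physical coordinates
(vt_t, tauc_t, L_t) the same classification is combined with the tension
sign of each stable branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DimensionlessParams
from .tension import bundle_tension
from .velocity import (
    ABCoefficients,
    Regime,
    ab_coefficients,
    branch_continuation,
    solve_velocity,
)

__all__ = [
    "PhaseGrid",
    "Transition",
    "regime_map_ab",
    "regime_boundaries_in_a",
    "contractility_map",
    "line_scan",
    "hysteresis_scan",
]


@dataclass
class PhaseGrid:
    """Tidy sweep result: one row per grid cell per root."""

    axes: dict
    records: pd.DataFrame


def regime_map_ab(a_grid, b_grid) -> PhaseGrid:
    """Roots, stability and regime per cell of an (a, b) grid."""
    rows = []
    for b in np.asarray(b_grid, dtype=float):
        for a in np.asarray(a_grid, dtype=float):
            sol = solve_velocity(ABCoefficients(a=a, b=b, y=0.0))
            for k, (u, s) in enumerate(zip(sol.roots, sol.stability)):
                rows.append(
                    {"a": a, "b": b, "root_index": k, "u": u, "stable": s,
                     "regime": sol.regime.value}
                )
    return PhaseGrid(
        axes={"a": np.asarray(a_grid, float), "b": np.asarray(b_grid, float)},
        records=pd.DataFrame(rows),
    )


def regime_boundaries_in_a(
    b: float, a_lo: float = 0.0, a_hi: float = 2.0, tol: float = 1e-4
) -> list[float]:
    """Regime-change values of a at fixed b, refined by bisection to ``tol``."""

    def regime_at(a):
        return solve_velocity(ABCoefficients(a=max(a, 0.0), b=b, y=0.0)).regime

    coarse = np.linspace(a_lo, a_hi, 201)
    labels = [regime_at(a) for a in coarse]
    boundaries = []
    for i in range(len(coarse) - 1):
        if labels[i] != labels[i + 1]:
            lo, hi = coarse[i], coarse[i + 1]
            r_lo = labels[i]
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if regime_at(mid) == r_lo:
                    lo = mid
                else:
                    hi = mid
            boundaries.append(0.5 * (lo + hi))
    return boundaries


def contractility_map(vt_grid, tauc_grid, L_grid) -> PhaseGrid:
    """Regimes and per-branch tension signs over a (vt_t, tauc_t, L_t) grid."""
    rows = []
    for vt_t in np.asarray(vt_grid, dtype=float):
        for tauc_t in np.asarray(tauc_grid, dtype=float):
            for L_t in np.asarray(L_grid, dtype=float):
                p = DimensionlessParams(vt_t=vt_t, tauc_t=tauc_t, L_t=L_t)
                ab = ab_coefficients(p)
                sol = solve_velocity(ab, p)
                for k, (u, s) in enumerate(zip(sol.roots, sol.stability)):
                    rec = {
                        "vt_t": vt_t, "tauc_t": tauc_t, "L_t": L_t,
                        "a": ab.a, "b": ab.b, "root_index": k,
                        "u": float(u), "vm_t": float(sol.vm_roots[k]),
                        "stable": s, "regime": sol.regime.value,
                        "T_t": np.nan, "T_sign": 0,
                    }
                    if s == "stable":
                        T = bundle_tension(u, p).T_t
                        rec["T_t"] = T
                        rec["T_sign"] = int(np.sign(T))
                    rows.append(rec)
    return PhaseGrid(
        axes={
            "vt_t": np.asarray(vt_grid, float),
            "tauc_t": np.asarray(tauc_grid, float),
            "L_t": np.asarray(L_grid, float),
        },
        records=pd.DataFrame(rows),
    )


@dataclass
class Transition:
    """A detected crossing along a line scan."""

    kind: str  # 'u_sign' or 'tension_sign'
    order: int  # 1 = discontinuous (jump / coexistence), 2 = continuous
    index: int  # step index of the crossing
    position: DimensionlessParams


def _interpolate(p0: DimensionlessParams, p1: DimensionlessParams, frac: float):
    return DimensionlessParams(
        vt_t=p0.vt_t + frac * (p1.vt_t - p0.vt_t),
        tauc_t=p0.tauc_t + frac * (p1.tauc_t - p0.tauc_t),
        L_t=p0.L_t + frac * (p1.L_t - p0.L_t),
    )


def line_scan(
    p_start: DimensionlessParams,
    p_end: DimensionlessParams,
    n_steps: int,
    start_branch: str | float = "auto",
) -> tuple[pd.DataFrame, list[Transition]]:
    """Full solution along a straight parameter path, with transition flags.

    Follows one stable branch by continuation; each u-sign or tension-sign
    change is labelled first order when the branch jumped or the scan
    passes through the coexistence window, second order otherwise.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    path = [_interpolate(p_start, p_end, k / (n_steps - 1)) for k in range(n_steps)]
    branch = branch_continuation(path, start_branch=start_branch)
    rows = []
    for bp in branch:
        T = bundle_tension(bp.u, bp.params).T_t
        rows.append(
            {
                "vt_t": bp.params.vt_t, "tauc_t": bp.params.tauc_t,
                "L_t": bp.params.L_t, "u": bp.u, "vm_t": bp.vm_t,
                "regime": bp.regime.value, "jumped": bp.jumped, "T_t": T,
            }
        )
    df = pd.DataFrame(rows)
    transitions = []
    in_coex = df["regime"] == Regime.COEXISTENCE.value
    for kind, col in (("u_sign", "u"), ("tension_sign", "T_t")):
        signs = np.sign(df[col].to_numpy())
        for i in np.nonzero(np.diff(signs) != 0)[0]:
            first = bool(df["jumped"].iloc[i + 1]) or bool(in_coex.iloc[i] or in_coex.iloc[i + 1])
            transitions.append(
                Transition(kind=kind, order=1 if first else 2, index=int(i), position=path[i])
            )
    return df, transitions


def hysteresis_scan(
    path: list[DimensionlessParams], start_branch_fwd="auto", start_branch_bwd="auto"
) -> pd.DataFrame:
    """Forward and backward continuation along ``path``.

    Inside a coexistence window the two sweeps select different branches;
    outside they coincide.  Returns one row per step with both selected u.
    """
    fwd = branch_continuation(path, start_branch=start_branch_fwd)
    bwd = branch_continuation(path[::-1], start_branch=start_branch_bwd)[::-1]
    return pd.DataFrame(
        {
            "vt_t": [p.vt_t for p in path],
            "tauc_t": [p.tauc_t for p in path],
            "L_t": [p.L_t for p in path],
            "u_forward": [b.u for b in fwd],
            "u_backward": [b.u for b in bwd],
            "regime": [b.regime.value for b in fwd],
        }
    )
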