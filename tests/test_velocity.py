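"""Velocity selection: root structure, stability, regimes, hysteresis."""

import numpy as np
import pytest

from cytobundle import (
    DimensionlessParams,
    Regime,
    ab_coefficients,
    branch_continuation,
    net_force,
    solve_velocity,
)
from cytobundle.velocity import (
    ABCoefficients,
    coexistence_onset,
    force_balance_residual,
    force_derivative,
)

from conftest import random_params


def test_ab_coefficients_worked_point():
    p = DimensionlessParams(2.0, 0.2, 1.0)
    ab = ab_coefficients(p)
    g04 = 0.8 - 1.8 * np.exp(-2.5)
    assert ab.y == pytest.approx(0.4)
    assert ab.a == pytest.approx(2 * (1 - g04), rel=1e-12)
    assert ab.b == pytest.approx(1 - g04, rel=1e-12)
    assert ab.a == pytest.approx(0.6955, abs=2e-4)
    assert ab.b == pytest.approx(0.3477, abs=2e-4)


def test_ab_limits():
    p0 = DimensionlessParams(0.0, 1.0, 2.5)
    ab0 = ab_coefficients(p0)
    assert ab0.a == 0.0
    assert ab0.b == pytest.approx(2.5)
    # long-lived crosslinks deplete completely: a, b -> 0
    pinf = DimensionlessParams(1.0, 1e8, 1.0)
    abinf = ab_coefficients(pinf)
    assert abinf.a < 1e-6 and abinf.b < 1e-6


@pytest.mark.parametrize(
    "a, expected_n, expected_signs, expected_regime",
    [
        (0.1, 1, [-1], Regime.U_NEGATIVE),
        (0.7, 3, [-1, 1, 1], Regime.COEXISTENCE),
        (1.3, 1, [1], Regime.U_POSITIVE),
    ],
)
def test_three_regimes_at_b027(a, expected_n, expected_signs, expected_regime):
    """Root structure of the selection equation along the b = 0.27 line."""
    sol = solve_velocity(ABCoefficients(a=a, b=0.27, y=0.0))
    assert len(sol.roots) == expected_n
    assert list(np.sign(sol.roots)) == expected_signs
    assert sol.regime == expected_regime
    for u in sol.roots:
        assert abs(force_balance_residual(u, sol.ab)) < 1e-10


def test_single_root_brackets():
    sol = solve_velocity(ABCoefficients(a=0.1, b=0.27, y=0.0))
    assert -1.05 < sol.roots[0] < -0.95
    sol = solve_velocity(ABCoefficients(a=1.3, b=0.27, y=0.0))
    assert 4.3 < sol.roots[0] < 4.5


def test_stability_labels():
    """Unique roots are stable; in coexistence the smaller u>0 root is unstable."""
    for a in (0.1, 1.3):
        sol = solve_velocity(ABCoefficients(a=a, b=0.27, y=0.0))
        assert sol.stability == ["stable"]
    sol = solve_velocity(ABCoefficients(a=0.7, b=0.27, y=0.0))
    assert sol.stability == ["stable", "unstable", "stable"]
    # stable solutions have opposing apparent-velocity signs
    stable_u = [u for u, s in zip(sol.roots, sol.stability) if s == "stable"]
    assert np.sign(stable_u[0]) != np.sign(stable_u[1])


def test_stability_matches_finite_difference_of_net_force(rng):
    for p in random_params(rng, 6):
        ab = ab_coefficients(p)
        sol = solve_velocity(ab, p)
        for u, vm in zip(sol.roots, sol.vm_roots):
            if abs(u) < 1e-6:
                continue
            h = 1e-6
            fd = (net_force(vm + h, p) - net_force(vm - h, p)) / (2 * h)
            assert force_derivative(u, ab) == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_root_count_scan_is_1_3_1():
    counts = np.asarray(
        [len(solve_velocity(ABCoefficients(a=a, b=0.27, y=0.0)).roots)
         for a in np.linspace(0.0, 2.0, 401)]
    )
    # pattern 1 -> 3 -> 1; the scan may land exactly on a boundary tangency
    # (2 merged roots, e.g. at a = 1), which belongs to the multi-root block
    assert 3 in counts
    assert counts[0] == 1 and counts[-1] == 1
    multi = counts > 1
    block_changes = np.nonzero(np.diff(multi))[0]
    assert len(block_changes) == 2  # one contiguous multi-root window


def test_roots_zero_net_force_cross_module(rng):
    for p in random_params(rng, 8):
        sol = solve_velocity(ab_coefficients(p), p)
        for vm in sol.vm_roots:
            assert abs(net_force(vm, p)) < 1e-9 * max(1.0, p.L_t)


def test_coexistence_window_matches_tangency():
    """Grid-refined regime boundaries coincide with the analytic tangency curve."""
    from cytobundle.phase_diagram import regime_boundaries_in_a

    for b in (0.2, 0.27, 0.5):
        bounds = regime_boundaries_in_a(b)
        assert len(bounds) == 2
        assert bounds[0] == pytest.approx(coexistence_onset(b), abs=2e-4)
        assert bounds[1] == pytest.approx(1.0, abs=2e-4)


def test_no_coexistence_for_steep_friction():
    assert np.isnan(coexistence_onset(1.5))
    for a in np.linspace(0.1, 1.9, 19):
        sol = solve_velocity(ABCoefficients(a=a, b=1.5, y=0.0))
        assert len(sol.roots) == 1


def _dashed_path(n=61, reverse=False):
    Ls = np.linspace(1.0, 4.0, n)
    if reverse:
        Ls = Ls[::-1]
    return [DimensionlessParams(2.0, 0.2, L) for L in Ls]


def test_dashed_line_hysteresis():
    """Forward and backward L sweeps disagree inside the bistable window."""
    fwd = branch_continuation(_dashed_path())
    bwd = branch_continuation(_dashed_path(reverse=True))[::-1]
    u_f = np.array([b.u for b in fwd])
    u_b = np.array([b.u for b in bwd])
    regimes = [b.regime for b in fwd]
    assert Regime.COEXISTENCE in regimes
    window = np.array([r == Regime.COEXISTENCE for r in regimes])
    assert np.any(np.abs(u_f[window] - u_b[window]) > 0.1)
    outside = ~window
    assert np.allclose(u_f[outside], u_b[outside], atol=1e-8)
    # first-order jumps recorded at the window exits
    assert any(b.jumped for b in fwd) and any(b.jumped for b in bwd[::-1])


def test_monostable_path_has_no_hysteresis():
    path = [DimensionlessParams(0.3, 0.5, L) for L in np.linspace(1.0, 3.0, 21)]
    fwd = branch_continuation(path)
    bwd = branch_continuation(path[::-1])[::-1]
    assert np.allclose([b.u for b in fwd], [b.u for b in bwd], atol=1e-10)
    assert not any(b.jumped for b in fwd)


def test_continuous_crossing_at_lower_treadmilling():
    """At smaller vt the u-sign change is continuous (second order), no window."""
    path = [DimensionlessParams(1.2, 0.2, L) for L in np.linspace(1.0, 6.0, 101)]
    fwd = branch_continuation(path)
    bwd = branch_continuation(path[::-1])[::-1]
    u_f = np.array([b.u for b in fwd])
    assert all(b.regime != Regime.COEXISTENCE for b in fwd)
    assert np.allclose(u_f, [b.u for b in bwd], atol=1e-10)
    assert u_f[0] < 0 < u_f[-1]
    assert np.max(np.abs(np.diff(u_f))) < 0.1  # no jump anywhere
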