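"""Bundle tension: closed forms vs the authoritative moment quadrature."""

import numpy as np
import pytest
from scipy.integrate import quad

from cytobundle import (
    DimensionlessParams,
    ab_coefficients,
    bundle_tension,
    dimensional_tension,
    solve_velocity,
    tension_map,
    tension_profile,
)
from cytobundle.profiles import crosslink_force_density, motor_force_density
from cytobundle.tension import (
    crosslink_tension,
    crosslink_tension_h_form,
    motor_tension,
    steady_motor_velocity,
    tension_from_moment,
)

from conftest import random_params


def motor_moment_quadrature(u, L_t=2.3):
    """Motor-only moment integral (1/L^2) int xi*fm dxi at apparent velocity u."""
    p = DimensionlessParams(vt_t=1.0, tauc_t=1.0, L_t=L_t)
    vm = p.vt_t - u * p.L_t
    val, _ = quad(
        lambda xi: xi * motor_force_density(xi, vm, p), 0, L_t,
        limit=200, epsabs=1e-13, epsrel=1e-13,
    )
    return val / L_t**2


@pytest.mark.parametrize("u", [0.35, 1.0, 4.0, -0.2, -1.0, -6.0])
def test_motor_tension_matches_moment_integral(u):
    """Both printed branches agree with the motor moment integral exactly."""
    assert motor_tension(u) == pytest.approx(motor_moment_quadrature(u), rel=1e-10)
    # L-independence of the reduction to u alone
    assert motor_tension(u) == pytest.approx(motor_moment_quadrature(u, L_t=0.7), rel=1e-9)


def test_motor_tension_continuity_and_asymptote():
    assert motor_tension(1e-8) == pytest.approx(0.5, abs=1e-7)
    assert motor_tension(-1e-8) == pytest.approx(0.5, abs=1e-7)
    assert motor_tension(0.0) == 0.5
    for u in (1e4, -1e4, 1e7):
        assert abs(motor_tension(u)) < 1e-3


def test_crosslink_tension_forms_agree(rng):
    """-vm*M(y) equals the regrouped h-based closed form at steady state."""
    for u in rng.uniform(-3, 3, 10):
        for y in np.geomspace(1e-3, 1e2, 10):
            assert crosslink_tension(u, y) == pytest.approx(
                crosslink_tension_h_form(u, y), rel=1e-9, abs=1e-12
            )


def test_bundle_tension_equals_moment_quadrature_all_regimes(rng):
    """Authoritative-definition equivalence across a sample of all 3 regimes."""
    sample = random_params(rng, 10) + [
        DimensionlessParams(2.0, 0.2, 1.0),
        DimensionlessParams(2.0, 0.2, 1.2),
        DimensionlessParams(2.0, 0.2, 4.0),
    ]
    regimes = set()
    for p in sample:
        sol = solve_velocity(ab_coefficients(p), p)
        regimes.add(sol.regime)
        for u, vm in zip(sol.roots, sol.vm_roots):
            res = bundle_tension(u, p)
            ref = tension_from_moment(vm, p)
            assert res.T_t == pytest.approx(ref, abs=1e-8)
            assert res.T_t == res.Tm_t + res.Tc_t
    assert len(regimes) == 3


def test_moment_equals_integrated_tension(rng):
    """(1/L^2) int xi*f dxi equals (1/L^2) int T(xi) dxi when int f = 0."""
    for p in random_params(rng, 3):
        sol = solve_velocity(ab_coefficients(p), p)
        vm = sol.vm_roots[0]
        xi = np.linspace(0, p.L_t, 4001)
        T = tension_profile(xi, vm, p)
        avg_T = np.trapezoid(T, xi) / p.L_t**2
        assert avg_T == pytest.approx(tension_from_moment(vm, p), abs=1e-8)


def test_tension_profile_vanishes_at_both_ends(rng):
    for p in random_params(rng, 5):
        sol = solve_velocity(ab_coefficients(p), p)
        for vm in sol.vm_roots:
            T = tension_profile(np.array([0.0, p.L_t]), vm, p)
            assert T[0] == 0.0
            assert abs(T[1]) < 1e-8 * max(1.0, p.L_t)


def test_tension_profile_requires_steady_state():
    p = DimensionlessParams(2.0, 0.2, 1.0)
    with pytest.raises(ValueError):
        tension_profile(np.linspace(0, 1, 5), 0.123, p)
    with pytest.raises(ValueError):
        bundle_tension(0.4, p)  # not a root


def test_zero_treadmilling_is_purely_compressive():
    """Without treadmilling the filament is compressed everywhere along xi."""
    p = DimensionlessParams(0.0, 1.0, 2.0)
    sol = solve_velocity(ab_coefficients(p), p)
    vm = sol.vm_roots[0]
    xi = np.linspace(0, p.L_t, 501)
    T = tension_profile(xi, vm, p)
    assert np.all(T <= 1e-12)
    # and by quadrature of the densities
    val, _ = quad(
        lambda x: x * (motor_force_density(x, vm, p) + crosslink_force_density(x, vm, p)),
        0, p.L_t,
    )
    assert val < 0


def test_zero_treadmilling_always_extensile(rng):
    """vt = 0 forces a negative bundle tension on every stable steady state."""
    for tauc_t in [0.1, 0.5, 1.0, 5.0]:
        for L_t in [0.5, 1.0, 2.0, 8.0]:
            p = DimensionlessParams(0.0, tauc_t, L_t)
            sol = solve_velocity(ab_coefficients(p), p)
            for u, s in zip(sol.roots, sol.stability):
                assert s == "stable"
                res = bundle_tension(u, p)
                assert res.T_t < 0
                assert res.classification == "extensile"


def test_dashed_line_sign_change():
    """Short filaments extend, long ones contract along the actomyosin line."""
    lo = bundle_tension(
        solve_velocity(ab_coefficients(DimensionlessParams(2, 0.2, 1.0))).roots[0],
        DimensionlessParams(2, 0.2, 1.0),
    )
    p4 = DimensionlessParams(2, 0.2, 4.0)
    hi = bundle_tension(solve_velocity(ab_coefficients(p4), p4).roots[0], p4)
    assert lo.T_t < 0 < hi.T_t
    assert lo.classification == "extensile"
    assert hi.classification == "contractile"


def test_dimensional_tension_yeast_ring():
    L = 1.4e-6
    T = dimensional_tension(0.2, 3, 20 / L, L, 7.2e-6)
    assert T == pytest.approx(1.21e-10, rel=0.02)
    assert dimensional_tension(1e-300, 3, 20 / L, L, 7.2e-6) == pytest.approx(0.0, abs=1e-30)
    assert dimensional_tension(-0.2, 3, 20 / L, L, 7.2e-6) < 0


def test_tension_map_structure():
    u = np.linspace(-2, 2, 81)
    y = np.geomspace(1e-3, 2.0, 21)
    T, contour = tension_map(u, y)
    assert T.shape == (21, 81)
    # continuity across u = 0
    j0 = np.argmin(np.abs(u))
    assert np.all(np.abs(T[:, j0 + 1] - T[:, j0 - 1]) < 0.1)
    # at negligible crosslink depletion every u < 0 state is extensile
    assert np.all(T[0, u < 0] < 0)
    # the contraction/extension boundary crosses the window at moderate y
    assert len(contour) > 0
    ys_on_contour = np.unique(contour[:, 1])
    assert ys_on_contour.size >= 5
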