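"""Force profiles, bundle tension, and the fission-yeast force scale.

For short filaments the crosslink force (applied away from the plus end)
flanks the motor force and the bundle extends; for long filaments the
motor depletion zone shifts motor forces toward the plus end and the
bundle contracts.  The dimensionless tension converts to Newtons through
T = T_t * z * rho_f * L^2 * fm0.
"""

import numpy as np

from cytobundle import (
    DimensionlessParams,
    ab_coefficients,
    bundle_tension,
    dimensional_tension,
    force_profile,
    solve_velocity,
    tension_profile,
)
from cytobundle.presets import fixtures

for L_t in (1.0, 4.0):
    p = DimensionlessParams(vt_t=2.0, tauc_t=0.2, L_t=L_t)
    sol = solve_velocity(ab_coefficients(p), p)
    u, vm = sol.roots[0], sol.vm_roots[0]
    res = bundle_tension(u, p)
    prof = force_profile(vm, p, n=9)
    T = tension_profile(prof.xi, vm, p)
    print(f"L = {L_t} vm0*tau_m:  u = {u:+.4f}, vm = {vm:.4f} vm0")
    print(f"  motor moment Tm = {res.Tm_t:+.4f}, crosslink moment Tc = {res.Tc_t:+.4f}")
    print(f"  bundle tension T_t = {res.T_t:+.4f}  -> {res.classification}")
    print(f"  tension profile min/max: {T.min():+.4f} / {T.max():+.4f} "
          f"(zero at both ends: {abs(T[0]) < 1e-12} / {abs(T[-1]) < 1e-8})")

fx = fixtures()["yeast_ring"]
T_N = dimensional_tension(fx["T_t"], fx["z"], fx["rho_f"], fx["L"], fx["fm0"])
print(f"\nFission-yeast ring (L = 1.4 um, rho_f*L = 20, z = 3, T_t = {fx['T_t']}):")
print(f"  T = {T_N:.3e} N = {T_N * 1e12:.0f} pN of contractile force,")
print("  the same order as measured cytokinetic ring tensions.")
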