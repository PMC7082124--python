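"""Velocity selection: roots of the force balance and their stability.

Solves S(u) = (1 - a) + b*u for the three illustrative (a, b) pairs and for
an experimentally motivated actomyosin parameter set.  u = (vt - vm)/L is
the apparent filament velocity: u > 0 means treadmilling outruns the
motors, u < 0 the reverse; in the coexistence regime the initial condition
decides which stable state the bundle adopts.
"""

from cytobundle import DimensionlessParams, ab_coefficients, solve_velocity
from cytobundle.velocity import ABCoefficients

print("Three regimes along the line b = 0.27:")
for a in (0.1, 0.7, 1.3):
    sol = solve_velocity(ABCoefficients(a=a, b=0.27, y=0.0))
    roots = ", ".join(f"u={u:+.4f} ({s})" for u, s in zip(sol.roots, sol.stability))
    print(f"  a = {a}: {sol.regime.value:12s} {roots}")

print("\nActomyosin bundle (vt = 2 vm0, tau_c = 0.2 tau_m, L = vm0*tau_m):")
p = DimensionlessParams(vt_t=2.0, tauc_t=0.2, L_t=1.0)
ab = ab_coefficients(p)
print(f"  depletion ratio y = {p.y:.3f} -> a = {ab.a:.4f}, b = {ab.b:.4f}")
sol = solve_velocity(ab, p)
for u, vm, s in zip(sol.roots, sol.vm_roots, sol.stability):
    print(f"  u = {u:+.4f}, motor velocity vm = {vm:.4f} vm0  ({s})")
print("  -> motors translocate faster than treadmilling (u < 0):")
print("     single filaments appear to move toward their minus ends.")
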