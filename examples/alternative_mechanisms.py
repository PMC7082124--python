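"""Comparing self-organization with buckling and end-dwelling mechanisms.

Buckling (flexible actin) contracts only when the motor/crosslink spacing
falls in a window set by the filament stiffness and motor detachment;
end-dwelling (microtubule motors pausing at plus ends) extends, but only
for slow treadmilling and long enough filaments.
"""

import numpy as np

from cytobundle.alternatives import (
    BucklingParams,
    buckling_bounds,
    buckling_tension,
    dwelling_comparison_map,
    dwelling_steady_state,
    dwelling_threshold_length,
)

bp = BucklingParams(n=100, l0=5e-8)
lo, hi = buckling_bounds(bp)
print(f"buckling window for n = {bp.n} myosin heads: "
      f"l0 in [{lo * 1e9:.1f}, {hi * 1e9:.1f}] nm")
print(f"  at l0 = {bp.l0 * 1e9:.0f} nm the bundle can buckle and pulls with "
      f"Fs = {buckling_tension(bp) * 1e12:.1f} pN per filament")

res = dwelling_steady_state(0.5, 4.0)
print(f"\ndwelling at vt = 0.5, L = 4: vm = {res.vm_t}, "
      f"T_dwell = {res.T_dwell_t} (extensile)")
print(f"no dwelling steady state below L = "
      f"{dwelling_threshold_length(0.5, tol=1e-3):.3f} (runaway motor pile-up)")

df = dwelling_comparison_map(np.array([0.5, 1.5]), np.array([3.0, 8.0]), tauc_t=1.0)
for _, row in df.iterrows():
    print(f"vt = {row['vt_t']}, L = {row['L_t']}: |T_self| = {abs(row['T_self']):.4f}, "
          f"|T_dwell| = {abs(row['T_dwell']):.4f} -> {row['dominant']} dominates")
print("fast treadmilling or long filaments favor the self-organization tension.")
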