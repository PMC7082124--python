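"""Named parameter sets for the worked examples.

``fixtures()`` returns the three canonical inputs used throughout the
package's examples and tests:

* ``"three_regimes"`` — the (a, b) triplets illustrating the three root
  regimes: b = 0.27 with a = 0.1 (single u < 0), 0.7 (coexistence), 1.3
  (single u > 0).
* ``"actomyosin_sweep"`` — the experimentally motivated actomyosin set
  vm0 = 50 nm/s, tau_m = 5 s, vt = 100 nm/s, tau_c = 1 s, with L swept
  from 250 nm to 1 um (dimensionless: vt_t = 2, tauc_t = 0.2, L_t from 1
  to 4).  rho_c0 is back-computed so that fm0/(2*kc*rho_c0*tau_c) equals
  the stated vm0.
* ``"yeast_ring"`` — the fission-yeast cytokinetic-ring magnitude check:
  L = 1.4 um, rho_f*L = 20, fm0 = 7.2e-6 N/m, kc = 3e-4 N/m, z = 3
  (hexagonal packing), with T_t = 0.2 and vm0 = 5 nm/s recorded as given
  inputs (the crosslink density behind that vm0 is not independently
  known).
"""

from __future__ import annotations

from types import MappingProxyType

from .params import DimensionalParams

__all__ = ["fixtures"]


def fixtures() -> dict:
    kc = 3e-4
    fm0 = 7.2e-6
    # dashed line: rho_c0 such that vm0 = fm0/(2 kc rho_c0 tau_c) = 50 nm/s
    vm0_dashed = 50e-9
    rho_c0_dashed = fm0 / (2 * kc * vm0_dashed * 1.0)
    dashed = DimensionalParams(
        vt=100e-9, tau_m=5.0, tau_c=1.0, L=250e-9, fm0=fm0, kc=kc,
        rho_c0=rho_c0_dashed, rho_m0=1e6, z=3, rho_f=20 / 250e-9, eta=1e-3,
    )
    return {
        "three_regimes": MappingProxyType({"b": 0.27, "a_values": (0.1, 0.7, 1.3)}),
        "actomyosin_sweep": MappingProxyType(
            {"params": dashed, "L_range": (250e-9, 1e-6), "vm0": vm0_dashed}
        ),
        "yeast_ring": MappingProxyType(
            {
                "L": 1.4e-6, "rho_f_L": 20.0, "rho_f": 20.0 / 1.4e-6,
                "fm0": fm0, "kc": kc, "z": 3, "T_t": 0.2, "vm0": 5e-9,
                "eta": 1e-3,
            }
        ),
    }
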