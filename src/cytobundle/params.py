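"""Parameter containers and unit handling.

The model lives in three dimensionless numbers: the treadmilling speed
``vt_t = vt/vm0``, the crosslink unbinding time ``tauc_t = tau_c/tau_m`` and
the filament length ``L_t = L/(vm0*tau_m)``, where
``vm0 = fm0/(2*kc*rho_c0*tau_c)`` is the speed at which the asymptotic motor
force density ``fm0`` balances the asymptotic crosslink friction
``2*kc*rho_c0*tau_c*vm``.  All lengths are rescaled by ``vm0*tau_m``, all
times by ``tau_m``, all velocities by ``vm0``.  Every other module consumes
:class:`DimensionlessParams`; SI quantities re-enter only through
:func:`cytobundle.tension.dimensional_tension` and
:func:`drag_force_estimate`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "characteristic_velocity",
    "nondimensionalize",
    "redimensionalize",
    "drag_force_estimate",
    "load_config",
]


def characteristic_velocity(fm0: float, kc: float, rho_c0: float, tau_c: float) -> float:
    """Speed vm0 = fm0 / (2 kc rho_c0 tau_c) at which asymptotic forces balance.

    Parameters are the asymptotic motor force per unit length [N/m], the
    crosslink spring constant [N/m], the equilibrium crosslink line density
    [1/m] and the crosslink unbinding time [s].
    """
    for name, v in (("fm0", fm0), ("kc", kc), ("rho_c0", rho_c0), ("tau_c", tau_c)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return fm0 / (2.0 * kc * rho_c0 * tau_c)


def drag_force_estimate(eta: float, L: float, vm0: float) -> float:
    """Order-of-magnitude viscous drag force eta * L * vm0 on a filament."""
    for name, v in (("eta", eta), ("L", L), ("vm0", vm0)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return eta * L * vm0


@dataclass(frozen=True)
class DimensionalParams:
    """Physical bundle parameters, SI units.

    vt: treadmilling speed [m/s]; tau_m / tau_c: motor / crosslink unbinding
    times [s]; L: filament length [m]; fm0: asymptotic motor force per unit
    length [N/m]; kc: crosslink spring constant [N/m]; rho_c0 / rho_m0:
    equilibrium crosslink / motor line densities [1/m]; z: number of
    interacting antiparallel neighbors; rho_f: filaments per unit bundle
    length [1/m]; eta: ambient viscosity [Pa s], optional (drag estimate
    only).
    """

    vt: float
    tau_m: float
    tau_c: float
    L: float
    fm0: float
    kc: float
    rho_c0: float
    rho_m0: float
    z: int
    rho_f: float
    eta: float | None = None

    def __post_init__(self):
        if self.vt < 0:
            raise ValueError(f"vt must be >= 0, got {self.vt}")
        for name in ("tau_m", "tau_c", "L", "fm0", "kc", "rho_c0", "rho_m0", "rho_f"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.eta is not None and self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if int(self.z) != self.z or self.z < 1:
            raise ValueError(f"z must be an integer >= 1, got {self.z}")
        if self.rho_f * self.L < 5:
            warnings.warn(
                f"rho_f*L = {self.rho_f * self.L:.3g} < 5: the bundle-averaged "
                "tension assumes many filaments per cross-section (rho_f*L >> 1)",
                stacklevel=2,
            )

    @property
    def vm0(self) -> float:
        """Characteristic velocity fm0/(2 kc rho_c0 tau_c) [m/s]."""
        return characteristic_velocity(self.fm0, self.kc, self.rho_c0, self.tau_c)


@dataclass(frozen=True)
class DimensionlessParams:
    """Model coordinates (vt_t, tauc_t, L_t) after rescaling by vm0 and tau_m."""

    vt_t: float
    tauc_t: float
    L_t: float

    def __post_init__(self):
        if self.vt_t < 0:
            raise ValueError(f"vt_t must be >= 0, got {self.vt_t}")
        for name in ("tauc_t", "L_t"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    @property
    def y(self) -> float:
        """Crosslink depletion ratio vt_t * tauc_t / L_t."""
        return self.vt_t * self.tauc_t / self.L_t


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Rescale to (vt_t, tauc_t, L_t) using vm0 and tau_m of ``p``."""
    vm0 = p.vm0
    return DimensionlessParams(
        vt_t=p.vt / vm0,
        tauc_t=p.tau_c / p.tau_m,
        L_t=p.L / (vm0 * p.tau_m),
    )


def redimensionalize(q: DimensionlessParams, vm0: float, tau_m: float):
    """Invert :func:`nondimensionalize`; returns (vt [m/s], tau_c [s], L [m])."""
    if not vm0 > 0 or not tau_m > 0:
        raise ValueError("vm0 and tau_m must be > 0")
    return q.vt_t * vm0, q.tauc_t * tau_m, q.L_t * vm0 * tau_m


def load_config(path) -> DimensionalParams | DimensionlessParams:
    """Read a YAML or JSON config with one `dimensional:` or `dimensionless:` block."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    has_dim = "dimensional" in data
    has_nd = "dimensionless" in data
    if has_dim == has_nd:
        raise ValueError(
            "config must contain exactly one of 'dimensional:' or 'dimensionless:'"
        )
    if has_dim:
        return DimensionalParams(**data["dimensional"])
    return DimensionlessParams(**data["dimensionless"])
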