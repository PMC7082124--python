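# cytobundle

Mean-field modelling of contraction and extension in disordered
motor–filament bundles.

Bundles of treadmilling cytoskeletal filaments (actin, microtubules) driven
by molecular motors and held together by transient crosslinks can contract
*or* extend, depending on where along each filament the motors and
crosslinks sit.  `cytobundle` implements a self-organization model in which
three well-characterized processes — filament treadmilling at speed `vt`,
motor binding/unbinding (time `τm`), and crosslink binding/unbinding (time
`τc`) — spontaneously deplete motors and crosslinks from depletion zones of
length `|vt − vm|·τm` and `vt·τc` next to the filament ends.  The resulting
force imbalance selects the motor sliding velocity `vm` self-consistently
and sets the sign of the bundle tension.

## Model

Lengths are rescaled by `vm0·τm` and times by `τm`, where
`vm0 = fm0/(2·kc·ρc0·τc)` is the velocity at which the asymptotic motor
force density `fm0` balances the asymptotic crosslink friction.  Three
dimensionless numbers remain: `ṽt = vt/vm0`, `τ̃c = τc/τm`,
`L̃ = L/(vm0·τm)`.  Steady states are the roots of the transcendental force
balance for the apparent filament velocity `u = (ṽt − ṽm)/L̃`:

    |u|·(1 − e^(−1/|u|)) = (1 − a) + b·u,
    a = ṽt·[1 − g(y)],  b = L̃·[1 − g(y)],  y = ṽt·τ̃c/L̃,
    g(y) = 2y − (1 + 2y)·e^(−1/y).

There are one or three roots; in the three-root regime the middle one is
unstable, producing bistability and hysteresis.  The bundle tension (in
units of `z·ρf·L²·fm0`) is the first position moment of the force density,
`𝒯̃ = 𝒯̃m + 𝒯̃c`, with closed forms for the motor and crosslink parts;
`𝒯̃ > 0` is contractile, `𝒯̃ < 0` extensile.  A headline prediction is that
`ṽt = 0` (no treadmilling) always gives extension — a discriminating test
against buckling- and end-dwelling-based contraction mechanisms, both of
which are also implemented for quantitative comparison.

## Worked example

```python
from cytobundle import (DimensionlessParams, ab_coefficients,
                        solve_velocity, bundle_tension, dimensional_tension)

p = DimensionlessParams(vt_t=2.0, tauc_t=0.2, L_t=1.0)   # short filaments
sol = solve_velocity(ab_coefficients(p), p)
res = bundle_tension(sol.roots[0], p)
print(sol.roots, res.T_t, res.classification)
```

prints

```
[-0.22803523] -0.21138360928887424 extensile
```

i.e. for short filaments the motors outrun treadmilling (`u < 0`) and the
bundle is under compression.  Repeating at `L_t=4.0` (growing the same
filaments from 250 nm to 1 µm at `vm0 = 50 nm/s`, `τm = 5 s`) gives
`u = +0.2697` and `𝒯̃ = +0.0027`: the bundle has crossed both the
velocity-reversal and the extension→contraction transitions.  Converting a
typical `𝒯̃ = 0.2` to physical units for the fission-yeast cytokinetic ring
(`L = 1.4 µm`, `ρf·L = 20`, `fm0 = 7.2e-6 N/m`, `z = 3`):

```python
dimensional_tension(0.2, 3, 20/1.4e-6, 1.4e-6, 7.2e-6)   # -> 1.21e-10 N
```

about 120 pN of contractile force, the order of magnitude measured in
protoplasts.  The `examples/` directory holds short narrative scripts, one
per capability (velocity selection, profiles and tension, phase-diagram
scans, the brute-force transport oracle, and the buckling/dwelling
comparisons); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library (`cytobundle solve|profile|tension|phase-ab|
phase-3d|scan|oracle|buckling-map|dwelling-map`), writing tidy CSV plus a
JSON manifest per run.

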