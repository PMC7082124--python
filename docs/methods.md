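# Methods

## Model

A bundle of rigid polar filaments of length `L` lies along one axis under
periodic boundary conditions.  Each filament treadmills at speed `vt`
(polymerization at the plus end, depolymerization at the minus end), so its
length is constant while its material moves.  Motors bind anywhere with
equilibrium line density `ρm0` and unbind after a mean time `τm`; while
bound to a pair of antiparallel filaments they walk toward plus ends at the
sliding velocity `vm` and, operating at stall, exert a force per unit
length proportional to their local density, `fm(ξ) = fm0·ρm(ξ)/ρm0`.
Crosslinks (density `ρc0`, unbinding time `τc`) behave as Hookean springs
of stiffness `kc` whose anchors do not slide: a crosslink of age `τ`
bridging antiparallel filaments is stretched by `2·vm·τ`, so the crosslink
force density is the age-weighted sum `fc = −2·kc·vm·∫τ·ρc(ξ,τ)dτ`.
Everything is mean-field: many motors and crosslinks per filament, no
density or velocity fluctuations, no filament bending (rigid rods), and
viscous drag is neglected (the worked actomyosin numbers put drag twelve
orders of magnitude below the predicted bundle tension; see
`drag_force_estimate`).

In the plus-end frame (coordinate `ξ` from the plus end) motors are
advected at `vt − vm` and crosslinks at `vt`.  Newly created filament
(ξ = 0) and newly created overlap carry no bound proteins, which produces
exponential depletion zones of lengths `|vt − vm|·τm` (motors, at the plus
or minus end depending on the sign) and `vt·τc` (crosslinks, at the plus
end).  The steady-state force densities have closed forms; their integral
gives the net force on a filament,

    F̃(ṽm) = L̃·[1 − S(u)] − ṽm·L̃·[1 − g(y)],

with `u = (ṽt − ṽm)/L̃`, `y = ṽt·τ̃c/L̃`, `S(u) = |u|(1 − e^(−1/|u|))` and
`g(y) = 2y − (1+2y)e^(−1/y)`.  All quantities are dimensionless: lengths
in `vm0·τm`, times in `τm`, velocities in `vm0 = fm0/(2·kc·ρc0·τc)`, force
densities in `fm0`.  This rescaling (module `params`) removes three
redundant dimensional parameters; the only places SI units reappear are the
tension conversion `𝒯 = 𝒯̃·z·ρf·L²·fm0` and the drag estimate.

## Velocity selection and stability

`F̃ = 0` is the transcendental equation `S(u) = (1 − a) + b·u` with
`a = ṽt(1 − g)`, `b = L̃(1 − g)`.  Because `0 ≤ S < 1` every root lies in
`[(a−1)/b, a/b]`; the solver brackets sign changes on a dense grid (20001
points over that interval padded by one unit, clipped to |u| ≤ 50 and
expanded once on failure) and polishes each bracket with Brent's method.
Roots closer than 1e-8 are merged and flagged marginal (tangency); the
possible tangential root at the kink `u = 0` (present iff `a = 1` within
1e-12) is tested explicitly because sign-change bracketing can miss it.
A root is stable iff `∂F̃/∂ṽm = S'(u) − b < 0`; values of the derivative
within 1e-10 of zero are labelled marginal.  Generic root counts are 1 or
3; the three-root regime has one `u < 0` and two `u > 0` roots, the smaller
positive one unstable.  The analytic boundaries of that regime are `a = 1`
(death of the negative root) and the tangency curve `a_c(b)` obtained from
the simultaneous conditions `S(u) = (1−a) + bu`, `S'(u) = b` (only for
`b < 1`; for `b ≥ 1` the sign change of `u` is continuous).  Grid-refined
phase-diagram boundaries are cross-checked against this tangency curve in
the tests.

Branch continuation along a parameter path follows the stable root nearest
in `u` to the previous step (the problem is one-dimensional, so no spectral
tracking is needed), flags a first-order jump when the followed branch
disappears (nearest stable root farther than 10x the recent step-to-step
variation, with an absolute floor of 0.1 to avoid misreading smooth drift),
and raises on nearest-root ties so the caller can refine the step.

## Bundle tension

The filament tension is `T(ξ) = −∫₀^ξ f`, vanishing at both ends at steady
state, and the bundle average over uniformly distributed intersection
coordinates is, after one integration by parts, the first position moment
`𝒯̃ = (1/L̃²)∫ ξ·[f̃m + f̃c] dξ`.  This moment integral is the
*authoritative definition*; the closed forms are an optimization validated
against adaptive quadrature to 1e-8 in the tests.  The motor part depends
on `u` alone (both branches continuous through `𝒯̃m(0) = 1/2`, decaying to
0 as `|u| → ∞`).  The crosslink part is `𝒯̃c = −ṽm·M(y)` with the moment
factor `M(y) = 1/2 − 3y² + (1 + 3y + 3y²)e^(−1/y)` derived directly from
the crosslink force profile (`M(0) = 1/2`, uniform crosslink coverage;
`M(∞) = 0`, full depletion) and `ṽm = (1 − S(u))/(1 − g(y))` from the force
balance.  `M` satisfies the algebraic identity `M = (1 − g)(2 + h)/4`,
where `h(y)` is the companion ratio whose denominator is identically
`1 − g`; the equivalent `h`-based closed form is kept as a cross-check
(`crosslink_tension_h_form`) rather than the computation path.
Classification uses a neutral band `|𝒯̃| ≤ 1e-9`.  Where two stable roots
coexist, tension is reported per branch; no automatic selection is made.

## Special-function numerics

`S`, `g`, `h` and `M` are evaluated through `expm1`-based restructurings
that avoid cancellation near their limits, with explicit underflow guards
(the `y → 0` and `u → 0` continuous extensions are returned exactly, and
`1/y` overflow falls back to the limit value).  `1 − g` and `M` lose
precision to cancellation at large `y` (`1 − g ~ 1/(6y²)`, `M ~ 1/(8y²)`),
so asymptotic series in `1/y` take over above `y = 100` and `y = 10`
respectively, with enough terms that the relative error stays below 1e-10
across the switchover; the same treatment covers `h` (series above
`y = 100`) and the motor tension branches (series above `|u| = 100`).
Switch points were fixed from the error analysis of the two expansions, not
tuned to data.

## Brute-force transport oracle

The `dynamics_oracle` module integrates the transport equations directly.
The age-structured crosslink density is reduced exactly to its first two
age moments (`m0`, `m1`): the force needs only `m1`, and the moment
hierarchy closes without truncation (`∂t m0 = −ṽt ∂ξ m0 + (1 − m0)/τ̃c`,
`∂t m1 = −ṽt ∂ξ m1 + m0 − m1/τ̃c`).  Space is discretized on a uniform
grid (default N = 2000 intervals) with first-order upwind differences and
an unsplit explicit Euler step at CFL 0.5 (including the source rate in the
step bound); the scheme is monotone, free of oscillations at the
depletion-zone kinks, and its interior mass budget telescopes exactly
(asserted per step in the tests).  The inflow boundary for the motor field
is re-selected each step from the current sign of `ṽt − ṽm`; at exact
equality no boundary condition is imposed.  The motor velocity relaxes as
`dṽm/dt = mobility·F̃` with the instantaneous discrete net force; this is a
fictitious descent dynamics for root finding and stability probing (the
model itself prescribes only the steady-state condition), with fixed points
at the force-balance roots, attraction exactly where `∂F̃/∂ṽm < 0`, a
divergence guard at `|ṽm| > 1e3`, and default mobility 1.

The upwind scheme's numerical diffusion biases the selected velocity by
O(Δξ); `steady_velocity_extrapolated` removes the leading term by
Richardson extrapolation across two grids (`2·vm(N) − vm(N/2)`), which the
oracle-equivalence tests use to compare against the force-balance roots at
1e-4 while the profile comparison stays at the single-grid O(Δξ) accuracy
(≤ 1e-2 sup-norm at N = 2000, with the first-order convergence rate
asserted).  Oracle test cases are drawn from a seeded Latin hypercube and
kept only when the targeted branch has `|u| ≥ 0.08` and crosslink depletion
length `≥ 0.05`, so both boundary layers are resolvable at that resolution;
fixed representatives of all three regimes (including both branches of a
bistable point) are always included.  These sizes are the package's
accuracy/runtime compromise for routine validation; the scheme converges
as O(Δξ) if more accuracy is wanted.

The `ṽt = 0` limit is handled exactly (no crosslink advection; uniform
crosslink force `−ṽm` for `ξ > 0`).  The closed-form crosslink profile is
then discontinuous at the single point `ξ = 0`, where the discrete steady
state correctly keeps the equilibrium value, so profile comparisons against
the oracle use `ṽt > 0`.

## Alternative mechanisms

*Buckling* (module `alternatives`): compressive segments between a motor
and a crosslink buckle when the spacing `ℓ0` lies in the window
`ℓ0⁻ = (kB·T·ℓp/(Fs·√L))^(2/3) < ℓ0 < ℓ0⁺ = (L·v·τm·ℓp)^(2/5)`; a buckled
bundle pulls with the minifilament stall force `Fs = n × 0.1 pN`, and zero
outside the window.  The upper-bound expression is used exactly as the
source model states it on SI magnitudes; it is dimensionally an empirical
boundary, and its exponent is a configurable field.  The motor detachment
time is taken to *increase* with head count as `τm(n) = 3 ms × 0.96^(−n)`
(the chance that all `n` intermittently attached heads release together
shrinks geometrically), which is the reading under which the buckling
window widens with `n`; the base, rate and exponent are configurable
fields, not hard-coded.  Comparison maps extrapolate both mechanisms to
one filament per cross-section; where two self-organization branches are
stable the larger `|𝒯̃|` is compared, and the motor force density scales
as `fm0 = Fs/ℓ0`.  Defaults: `kB·T = 4.1e-21 J` (room temperature),
`ℓp = 10 µm`, `L = 5 µm`, `v = 200 nm/s`.

*End-dwelling*: motors reaching the plus end dwell for `τm` while all
other attachment dynamics is instantaneous (uniform bulk densities, no
depletion zones).  The force balance is linear,
`F̃ = (2 − L̃)·ṽm + L̃ − 2ṽt`, giving `ṽm = (L̃ − 2ṽt)/(L̃ − 2)` and
`𝒯̃dwell = −(1 − ṽt)/(2(L̃ − 2))` for `ṽt < 1, L̃ > 2` (always extensile);
`ṽt ≥ 1` removes dwelling (`ṽm = 1`, zero tension); `L̃ < 2` leaves the
motor-accumulation feedback unopposed and no steady state exists.
Doubly-dwelling motors are excluded by construction (antiparallel sliding
rips them off one filament).  The threshold length is also measured
dynamically, by bisection on the converge/diverge outcome of the velocity
relaxation — the route `scripts/acceptance.py` takes, so the reported
threshold is computed rather than read off the case split.

## Worked parameter sets

`presets.fixtures()` records three canonical inputs: the (a, b) triplets of
the three-regime illustration (b = 0.27; a = 0.1, 0.7, 1.3); the
actomyosin "dashed line" (`vm0 = 50 nm/s`, `τm = 5 s`, `vt = 100 nm/s`,
`τc = 1 s`, L swept 250 nm → 1 µm, i.e. `ṽt = 2`, `τ̃c = 0.2`,
`L̃ = 1 → 4`), with `ρc0` back-computed from the stated `vm0` since it is
not independently known; and the fission-yeast ring magnitude check
(`L = 1.4 µm`, `ρf·L = 20`, `fm0 = 7.2e-6 N/m`, `kc = 3e-4 N/m`, `z = 3`),
where `𝒯̃ = 0.2` and `vm0 = 5 nm/s` are treated as given inputs for the
unit conversion because the crosslink density behind them is likewise not
independently specified.

## Known limitations

Mean-field only: no finite-number fluctuations, no filament positional
ordering, one-dimensional bundles, constant unbinding rates (no force
dependence), motors always at stall.  The dwelling no-steady-state regime
is reported as such rather than regularized.  The buckling comparison
inherits the empirical character of the `ℓ0⁺` bound.  Passing the oracle
equivalences shows the closed forms and the transport dynamics agree with
each other under the model's assumptions; it does not by itself validate
those assumptions against real bundles.
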