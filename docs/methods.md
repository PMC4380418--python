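# Methods

## Thermal model

The sample bolus and the capillary wall engaged with a heater block are
treated as one isothermal lump (quasi-lumped capacitance).  Convection and
the internal resistance of the bore are neglected; the block is a
constant-temperature reservoir.  Heat enters through the half-cylinder
radial conductive resistance of the tube wall,
`R = ln(d_o/d_i)/(π L k_c)`, and charges the combined capacitance
`C = L(π/4)[ρ_s c_s d_i² + ρ_c c_c (d_o² − d_i²)]`.  The response to a step
in drive temperature is the bounded exponential with `τ = R·C`; the engaged
length cancels, so τ is a property of the tubing cross-section and fill.
Bore inclusions (e.g. the two legs of a fine thermocouple) substitute their
own `ρ·c_P` for the water they displace; the junction bead is ignored
(its contribution is below 2 % of the bore capacitance).  Contact
resistance between tube and block defaults to zero — the tube is assumed
tensioned firmly into its groove — but an additive series term is
accepted everywhere a resistance is computed.

Default property table (overridable per config): water ρ = 997 kg/m³,
c_P = 4181 J/(kg·K); FEP k = 0.195 W/(m·K), ρ = 2150, c_P = 1172;
polycarbonate k = 0.20, ρ = 1200, c_P = 1200; aluminum c_P = 897,
k = 205; thermocouple wire (chromel/alumel average) ρ = 8700, c_P = 450.
With these handbook values the a-priori τ is 1.60 s for the 406/794 µm FEP
capillary and 0.603 s for the thermocouple-instrumented 562/750 µm
polycarbonate capillary (within ~2 % of the 0.590 s analytic reference
value for that geometry).

For a finite block, the passive two-lump equilibrium is the
capacitance-weighted mean of block and sample temperatures; with the
reference 55 g aluminum blocks (C_B ≈ 49.3 J/K) and a 4 µL engaged sample
(C_SC ≈ 0.045 J/K), engaging a 96 °C block against a 60 °C sample perturbs
the block by under 0.04 °C, justifying the reservoir assumption.

## Wheel kinematics

Moves follow a trapezoidal velocity profile with acceleration `a` and
cruise velocity `v` (defaults 6103.52 µsteps/s² and 4000 µsteps/s):
`t = d/v + v/a` when the move reaches cruise (`d ≥ v²/a`), else the
triangular `t = 2√(d/a)`.  The microstep length of a one-segment move is
never inferred from motor specifications (microstep resolution is
drive-dependent); it is calibrated by inverting the profile at one observed
single-segment transition time.  Inverting at 1.32 s gives
d = 2658.56 µsteps and predicts 1.98 s and 2.65 s for two- and
three-segment moves — successive moves differ by exactly `d/v` = 0.665 s in
the cruise regime.  Calibration observations shorter than `2v/a` are
inverted with the triangular formula so the forward/inverse pair always
round-trips; this boundary is the physically consistent one even though the
naive trapezoidal inversion would return d = 0 at `t = v/a`.

The wire harness limits cumulative rotation to ±270°.  The planner picks
the direction with fewer segments, breaks ties toward reducing |twist|,
takes the long way when the short way would exceed the limit, and raises
(naming the twist state) when neither direction is legal.  Angular
convention: segments 0..n−1 counterclockwise, centers at (i+½)·360/n, the
bolus fixed at lab angle 0; positive twist is counterclockwise.

A drive-temperature schedule for any point on the bolus is derived from the
planned motion: the point at angular offset δ from bolus center changes
blocks when a block edge sweeps past it, so leading and trailing bolus
edges switch `2δ/ω` apart at cruise speed.  Inter-block gaps (felt-filled,
traversed in well under a second) are modelled as adiabatic holds: the
sample keeps its temperature while no block is engaged.  Edge-crossing
times are refined by root finding on the engagement angle to ≈1 ns.

## Simulation and settle metrics

Within each constant-drive interval the response is evaluated in closed
form, so the output step `dt` (default 0.1 s, matching ~10 Hz logging)
affects sampling only, never accuracy.  Heating and cooling share one τ by
default; an asymmetric pair is supported because fitted rise and fall
constants typically differ by a few percent.  Settle time to within a gap
`ΔT_target` of the final temperature after an initial gap `ΔT_initial` is
`τ·ln(ΔT_initial/ΔT_target)`; effective ramp rates divide the temperature
moved by rotation-plus-settle time.

## Trace analysis

Logged cycling traces are reduced in four steps.

1. **Segmentation.** Plateau levels are 10 %-trimmed means of the samples
   below/above the trace midpoint; thresholds default to 10 % and 90 % of
   the plateau span.  A hysteresis state machine emits one event per full
   band traversal (plateau noise cannot trigger spurious segments), and
   each transition keeps half of each neighbouring plateau for baseline
   estimation.
2. **Baseline correction and averaging.** Each segment is affinely mapped
   so its plateau asymptotes match the across-segment means, aligned on its
   interpolated 50 %-crossing time (exact for noiseless shifted copies),
   interpolated onto a common grid, and averaged pointwise.
3. **Two-parameter fit.** (τ, t₀) are seeded by solving the response model
   exactly at the two data points nearest 33 % and 80 % of span — interior
   points chosen to be robust to noise at both ends — then refined by least
   squares over the full segment between plateaus (equivalent to maximizing
   R²).  The trust-region refinement never degrades the seed; convergence
   tolerances are set well below 1e-6 s.  On noiseless data the seed is
   already exact, so recovery is limited only by machine precision.
4. **Reporting.** Settle times and rates to within 1 °C and 0.1 °C wrap the
   closed forms above into a rise/fall table.

## Protocol compilation

Protocol temperatures are assigned to wheel blocks in increasing
temperature order; a spare segment, when available, is reserved unheated
for sample load/unload, otherwise loading uses the coolest block.  A
five-temperature protocol on a four-segment wheel is expressed with a
mid-run setpoint change: the affected block hosts both temperatures, its
stabilization allowance (user-supplied, not modelled from physics) runs
concurrently with cycling, and compilation only verifies it completes
before the block is next used.  Dwell timers start at rotation completion;
thermal settling is reported by validation (a dwell shorter than 3τ draws a
warning), not added to the timeline.  The initial load rotation is included
in the total; the final unload rotation is not.  Validation also warns when
adjacent heated segments differ by more than 60 °C, the sustainable limit
between neighbouring zones in still air.

## Cleaning ledgers

The five shipped protocols (A–E) encode the between-run cleaning sequences
as ordered fluidic steps with feature flags (valve rotation wash, final
inlet flush, full/shorter/no dedicated wheel wash, inlet wash).  Reagent
totals sum consumed volumes over repetitions; per-step volumes the
narrative does not state individually (for example the 3 × 30 µL inlet
bleach washes and the flush volumes) are reconstructed so protocol totals
match the published feature-comparison table, and are marked
`reconstructed` in the data files.  Durations are priced from a timing
config — flow rates per flow path, a valve actuation time, and 15 s per
manual agitation (midpoint of the stated 10–20 s range) — calibrated once
against the published per-protocol durations and shipped as a fixture; the
calibrated estimates land within 10 % of all five published times.  Water
totals count syringe-delivered water only.

## Synthetic data

`generate_trace` emulates an in-capillary thermocouple log: closed-form
response to a square-wave (or arbitrary) drive schedule, sampled at 10 Hz,
plus seeded i.i.d. Gaussian noise (default σ = 0.3 °C, which reproduces
fitted R² near 0.992 on single transitions) and optional linear sensor
drift.  It does not emulate non-ideal block handoffs, friction heating
during rotation, bolus displacement, or sensor lag, so passing
parameter-recovery tests demonstrate correctness of the pipeline under the
model's own assumptions, not robustness to every artefact of real logs.
All randomness flows through one seeded generator; every stochastic test is
reproducible.

## Problem sizes and numerical choices

The test suite and acceptance script run the models at their natural sizes
(26- and 32-cycle protocols, five-cycle characterization traces, 100
noisy-recovery replicates); the ODE cross-check integrates explicit Euler
at dt = 0.1 ms over ~15 s schedules, keeping its own discretization error
below the 0.01 °C comparison tolerance.  Ties in rotation direction are
broken toward reducing harness twist; degenerate inputs (zero-length
engagement, equal diameters, empty schedules, constant traces) either
return exact limits or raise informative validation errors, as exercised in
the tests.

## Known limitations

* Heater PID dynamics, free-convection losses, and the block-reheat
  undershoot transient are out of scope; setpoint-change stabilization is a
  user-supplied constant.
* The single-τ first-order model cannot represent the early-transition
  deviation caused by non-instantaneous block handoff; the bolus-offset
  schedule is the only non-ideality mechanism provided.
* Printed three-significant-figure transition times are self-consistent
  only to their rounding; single-point calibration reproduces them to
  ~0.01 s, not exactly.
* Cleaning durations depend on a calibrated timing fixture; absolute times
  for other pump/tubing combinations require recalibration.
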