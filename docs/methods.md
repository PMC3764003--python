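# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `emboflow`.  It is the package's own account of its science;
all numbers quoted here are computed by the test suite or
`scripts/acceptance.py`.

## Problem and scope

The package studies clot embolization in the aortic arch under two inlet
conditions: normal sinus rhythm and atrial fibrillation (AF), the latter
characterized by a 30% reduction in cardiac output and a 40% shorter
cardiac cycle.  The quantity of interest is *stroke propensity*: the
percentage of released clots whose trajectories end in the left common
carotid artery (LCCA).

The arch is modeled as a **planar (2-D) reduction** of the 3-D vessel: a
180° curved channel of width `D_AA` with three branch stubs leaving the
outer wall, plus straight inlet and outlet legs.  The planar reduction is
what makes the problem solvable at desk scale; the mechanism under study —
inertial crossing of streamlines by finite-size clots near branch mouths,
modulated by the waveform — survives in the plane.  Quantitative 3-D
propensity values are *not* reproducible in this reduction; the package's
claims about the AF effect are directional (AF ≥ normal at high ejection
speed, normal WSS > AF WSS), and its tests assert exactly that.

## Geometry

Diameters (Case I / Case II): ascending aorta 29 / 27.5 mm, BCA 19 / 11.4,
LCCA 14.3 / 7.5, LSA 16.7 / 10.1 mm.  The two cases bracket the observed
range of carotid diameters.  Quantities the source morphometry does not
dimension are package defaults, chosen once for plausible arch
proportions and configurable:

* centerline bend radius `2 × D_AA`;
* branch take-offs at 60°, 90°, 120° along the bend, directed radially
  outward, stubs of length `3 ×` their diameter;
* inlet/descending legs of length `D_AA`.

The domain is rasterized to a cell-centered mask (default spacing
`D_AA/32`); the rasterized planform area converges to the analytic area of
the parametric shape under refinement, and every port's cell span matches
its diameter to within about one cell.

## Blood and inlet waveforms

Blood is Newtonian with ρ = 1060 kg/m³ and μ = 3.5 mPa·s, giving
ν = 3.30 × 10⁻⁶ m²/s.  This single property set simultaneously reconciles
the four target dimensionless numbers: Womersley α = (D/2)√(2π/(Tν)) =
20.0 (T = 1 s) and 25.8 (T = 0.6 s) at D = 29 mm; peak Reynolds
UD/ν = 6500 at U = 0.74 m/s; cycle-mean Reynolds ≈ 1200 at a 5.5 L/min
cardiac output.

The waveform family is a half-sine systolic pulse, zero in diastole:
`u(t) = U_peak sin(π t / T_s)` for `0 ≤ t ≤ T_s`.  `T_s` is solved from
the cardiac-output constraint `CO = (2/π) U_peak (T_s/T) × πD²/4`, giving
T_s ≈ 0.295 s (normal) and 0.286 s (AF).  Only the published constraints
(cycle length, CO, peak, mean) are enforced — the true waveform shape
(diastolic backflow, dicrotic notch) is unknown and not modeled.  The
family is pluggable so alternative shapes can be tested.

Clot-ejection moments are defined on the waveform: systole onset, the
first upstroke crossing of `U_peak/2` (analytically `T_s/6` for this
family), and peak flow (`T_s/2`).

## Flow solver

Incompressible Navier–Stokes on a staggered (MAC) grid over the masked
domain:

* first-order upwind advection, explicit central diffusion;
* pressure projection by a direct sparse solve of the masked Poisson
  equation (prefactorized LU; one cell pinned to fix the constant);
  post-projection divergence is machine-level;
* plug inlet velocity from the waveform; no-slip walls imposed at wall
  faces, with ghost-cell reflection for tangential components
  (second-order wall placement);
* prescribed-flux plug outflow at every outlet, the fraction of the
  instantaneous inlet flow per outlet being fixed: defaults
  BCA 0.15, LCCA 0.075, LSA 0.075, descending 0.70.  The measured splits
  behind these are not published, so the values are literature-typical
  arch fractions and a sensitivity knob.  Outlet speeds are rescaled each
  step from the discrete inlet flux, so global mass balance is exact by
  construction.

Time step from an advective CFL number of 0.4 at peak inlet velocity
(~2100 steps per normal cycle at `D_AA/32`).  Cycle runs hold the last
cycle as a periodic snapshot history (100 snapshots/cycle) and report the
cycle-to-cycle L2 velocity change as a periodicity diagnostic; three
cycles (two transient + one recorded) suffice for this diagnostic to fall
by roughly two orders of magnitude under the normal waveform.

Validation: plane Poiseuille (centerline/mean ratio 1.5 within 2%; wall
shear stress 6μU/h within 5%, second-order convergent), and the
oscillatory body-force channel at α = 5 against the analytic Womersley
profile (≤5% L2, normalized by the cycle-peak profile norm — pointwise
relative error is ill-defined near flow reversal).

An optional constant-coefficient Smagorinsky eddy viscosity
(`C_s = 0.17`) stands in for flow-model sensitivity studies; it is a
toggle whose effect on propensity can be reported, not a validated
turbulence closure.  The default is laminar: at a cell Reynolds number of
order 10² the upwind scheme's numerical diffusion already regularizes the
field, so the 2-D solver should be read as a smooth surrogate of the
disturbed 3-D flow.

Wall shear stress is extracted per wall-adjacent cell as
`τ_w = μ |u_t(h/2)| / (h/2)` with an approximate arc-length coordinate
from nearest-neighbor chaining of wall segments.

## Clot transport

Each clot is a point particle with a finite collision radius (diameter
2–6 mm, density 1080 kg/m³).  Forces: Schiller–Naumann drag
(`C_d = 24/Re (1 + 0.15 Re^0.687)`, 0.44 above Re = 1000; Stokes in the
limit), pressure-gradient (fluid-acceleration) force, and added mass with
`C_am = 0.5`.  Gravity/buoyancy is available but off by default — the
orientation of the planar arch relative to gravity is not defined by the
reduction.  The exact force formulation used by the original 3-D study is
not available; this is the standard discrete-phase set.

Integration is a midpoint scheme with exponential (integrating-factor)
treatment of the drag term: unconditionally stable in the stiff-drag
limit, exact for Stokes relaxation in uniform flow, and second-order for
the fluid forces.  Two oracle checks pin it down: slip relaxation matches
`exp(−t/τ_p)`, `τ_p = ρ_p d²/(18μ)` (0.069 s at d = 2 mm) to well under
1%, and a density-matched tracer in solid-body rotation conserves its
orbit radius to <0.01% per revolution.  The fluid acceleration is
estimated by differencing the sampled velocity along the local fluid path
over a *fixed* interval (1 ms), so the force field is independent of the
integration step; with this choice, halving the particle step leaves the
exit branch of a 50-clot probe ensemble unchanged.

Wall contact projects the center back to a half-diameter standoff along
the analytic signed-distance gradient and zeroes the inward normal
velocity (tangential slide); repeated projection handles corners.  Port
channels are extended beyond their outlet planes in the distance field so
wall handling never blocks an exit.

Transport is **one-way** by default: clots are advanced through the
frozen periodic flow history (released singly in the physical experiment,
the suspension is dilute).  A minimal particle-source-in-cell two-way
option deposits the clot's drag-impulse reaction on the carrier
(bilinear weights, fluid slab of thickness `d_p`) for fidelity
experiments; it is stable but carries the planar reduction's depth
ambiguity and is not validated.

## Release ensemble and statistics

Releases form a full factorial grid: 17 equispaced positions on the inlet
chord spanning ±40% of the inlet radius, ejection speeds (default: 10
values uniformly spanning 0–0.8 m/s; a 0.1–0.7 m/s step-0.1 sweep is a
named preset; "moderate"/"high" map to the per-condition cycle-mean and
peak velocities), diameters 2–6 mm, and the three ejection moments —
2550 specs at study defaults.  Clots are released `0.1 D_AA` above the
inlet plane with velocity directed along the inlet axis.  Integration
horizon: 5 cardiac cycles after release.

Outcomes: each trajectory terminates as an exit through one of the four
ports or as retained at the horizon.  The propensity statistic counts
where the trajectory *ended up*: a clot that entered a branch stub and is
still inside it at the horizon counts as captured by that branch — with a
finite stub and weak intra-branch flow during diastole, demanding a
crossing of the stub-end plane would censor genuine carotid emboli.  The
headline statistic counts LCCA captures only (the left-carotid pathway);
BCA and LSA captures are tabulated alongside.  Per-stratum propensities
over 17-clot strata are multiples of 100/17 ≈ 5.9% by construction and
are reported to one decimal.

## Problem sizes used in tests and the acceptance script

Grid `D_AA/32` (~11.5k fluid cells), three cardiac cycles per condition,
100 snapshots/cycle, particle step 1 ms, high-speed ensembles of
17 × 5 = 85 clots per condition.  These sizes keep a full two-condition
experiment within a few minutes on one CPU while leaving the directional
findings stable under step halving and grid refinement checks.

## Known limitations

* The planar reduction cannot reproduce 3-D secondary (Dean) flows,
  helical arch flow, or circumferential release positions; published 3-D
  propensity magnitudes (tens of percent under AF) are out of reach, and
  only directional comparisons are claimed.
* The waveform is a constrained idealization; beat-to-beat cycle-length
  irregularity (a defining feature of AF) is not modeled.
* Outlet flow-split fractions are assumed constants, not measured data.
* The eddy-viscosity toggle is a sensitivity device, not a turbulence
  model; the laminar default under-resolves disturbed flow near branch
  mouths.
* Clots are rigid spheres: no deformation, breakup, aggregation, or
  adhesion; particle–wall contact is a geometric constraint, not a
  biomechanical model.
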