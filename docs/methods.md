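# Methods

`wingflow` simulates the two-dimensional, unsteady, incompressible flow
around a rigid flapping wing cross-section and reduces the result to lift
and drag coefficient histories and cross-section comparison statistics.
This note records the model, the numerical scheme, the defaults and why they
were chosen, and what the desk-scale configurations can and cannot show.

## Flow model

The fluid obeys the incompressible Navier–Stokes equations

    ∂u/∂t + (u·∇)u = −(1/ρ)∇P + ν∇²u,     ∇·u = 0,

with constant density ρ and kinematic viscosity ν; gravity is absorbed into
the gauge pressure. The wing is a rigid body moving with prescribed
kinematics. Instead of a body-fitted moving mesh, the solid is imposed on a
*fixed* Cartesian grid by Brinkman volume penalization: a solid-fraction
field χ ∈ [0, 1] marks the section, and the momentum equation acquires the
forcing −(χ/η)(u − u_body), which drives the fluid inside the mask toward
the local rigid-body velocity on the time scale η. Both descriptions
converge to the same continuum problem as η → 0 and the grid refines; the
penalization form needs no remeshing, handles arbitrary section shapes
uniformly, and yields the hydrodynamic force as the volume integral of the
forcing — here evaluated exactly as the momentum the penalization substep
removes from the fluid,

    F = ρ ∫ (χ/η)(u − u_body) dA   (reaction on the body, per unit span).

Flows considered are laminar (section Reynolds numbers of order 10–10³); no
turbulence model is used.

## Discretization

* **Grid.** Uniform staggered (MAC) arrangement: pressure at cell centres,
  velocity components on cell faces. Square cells enforced to 1%.
* **Advection.** Second-order upwind-biased differences of the advective
  form (each one-sided stencil is individually second order). A plain
  second-order centred variant can be selected for low cell-Péclet flows;
  measured on the Taylor–Green vortex the two agree to within 0.5% at the
  resolutions used, so the upwind default stands everywhere.
* **Diffusion.** Second-order centred, explicit.
* **Time integration.** The advective–diffusive right-hand side, including
  the lagged pressure gradient (incremental-pressure form), is advanced with
  a two-stage Heun (RK2) update; the penalization substep and the pressure
  projection follow once per step. The overall splitting is formally first
  order, but the two-stage update removes the O(Δt) advective dissipation
  that a forward-Euler step would impose — with CFL-limited steps that error
  behaves like a first-order-in-space viscosity and is the difference
  between ~40% and <1% spurious kinetic-energy decay on the Taylor–Green
  test at 256².
* **Penalization.** Implicit form
  u ← (u* + (Δt χ/η) u_body) / (1 + Δt χ/η),
  identical to the explicit forcing to O(Δt) and stable for any η. The
  in-solid velocity mismatch is proportional to η (verified by halving).
* **Projection.** The pressure correction solves a standard five-point
  Poisson problem; the discrete divergence after projection is at round-off
  (the test suite asserts ≤ 10⁻⁸·V/ΔX every step). Fully periodic domains
  use an FFT solve, the closed tank a DCT (all-Neumann) solve, and the
  open/channel modes a pre-factorized sparse LU.
* **Time step.** Advective and diffusive stability budgets combine
  additively,

      Δt = 1 / ( V_ref/(CFL_max ΔX) + 4ν/ΔX² ),
      V_ref = max(|Vx| + |V∞|, |Vy|, max|u| + max|v|),

  so Δt equals the kinematic CFL value when diffusion is negligible and the
  explicit diffusive limit ΔX²/(4ν) at rest, and never exceeds either; a
  configured penalization time η additionally caps Δt. A plain minimum of
  the two caps was measured to be transiently unstable when both mechanisms
  are near their individual limits. Default CFL_max is 0.5 in the presets.

### Boundary conditions

* *Forward flight (`open`)*: uniform inflow at speed V∞ directed −x on the
  right boundary, zero-gauge-pressure outflow on the left, free-slip top and
  bottom. The domain is 22c × 11c (88 mm × 44 mm at c = 4 mm) with the
  stroke centred.
* *Hover validation (`closed`)*: no-slip on all four walls, replicating a
  still tank.
* *Verification modes*: fully periodic, and a periodic-x channel with
  optional moving lid (Couette and Taylor–Green tests).

### Penalization time scale

If the case does not fix η, the solver sets η = 0.02·Δt_nominal, making the
implicit substep effectively direct forcing. This matters: with a soft
penalization (η ≈ 0.35 Δt) the section leaks its bound circulation and the
hovering benchmark's lift coefficient drops by ~30% relative to the stiff
limit; lift saturates once η ≲ 0.03 Δt while drag moves by only a few
percent. An explicitly configured η is also honoured as a Δt cap (the
documented rule), which the auto default — an internal solver choice, not a
configuration value — does not impose.

### Body masking

Section polygons are decimated to the grid scale, transformed to the body
frame, and each velocity-face cell near the body is probed with an n×n
stratified sub-sample (default n = 3) to produce a fractional χ. Rasterized
area matches the polygon area to well under 1% at solver resolutions, and
the mask of a symmetric section is exactly symmetric under half-turn
rotation.

## Kinematics

Forward flight maps the three wing-base rotations to planar section motion:
stroke and deviation become translations at the pivot radius r0 = 6.61 mm,

    x(t) = r0 θ1A cos(ωt + φ1),   y(t) = r0 θ2A cos(ωt + φ2),

(amplitudes in radians; φ1 = φ2 = 0 by default, a straight inclined stroke
path), and pitch stays angular, θ3(t) = θ3A sin(ωt). Frequency and
amplitudes are f = 150 Hz, θ1A = 110°, θ3A = 24°; θ2A is tabulated against
flight speed (10°, 15°, 20°, 24°, 26° at 1–5 m/s, linearly interpolated
between). The cycle therefore starts at zero incidence and zero speed,
peaks in both at the half-stroke midpoints, and reverses at τ = f·t = 0.5.

One orientation subtlety is fixed by the physics: the freestream arrives
from +x (the leading edge points into it), so a *positive angle of
incidence* — nose raised into the oncoming flow, the lift-producing sense —
is a clockwise geometric rotation of the chord. The solver's placement
angle is therefore −θ3(t) in forward flight. With the opposite sign the
mean lift is negative at every speed and no thrust regime exists; with this
sign the model produces positive cycle-averaged lift and the expected
transition from net thrust at low flight speed to net drag at high speed.

The hovering-validation mode drives the benchmark case: translation
x = r0 θ1A cos(ωt) (the published phase π/2 is the conventional 90°
pitch–translation offset of normal hovering, measured against the pitch
sinusoid), no y motion, and plate orientation 90° + θ3A sin(ωt) from the
x-axis — near-vertical at the stroke reversals, inclined 45° at mid-stroke,
with the upper edge leading on both half-strokes.

Analytic velocities are exact derivatives and match central finite
differences to 10⁻⁶ relative; all motions are exactly periodic in τ.

## Force normalization

Coefficients use the flapping convention: the reference speed V_mag is the
wing's *peak translational speed* over the cycle (dense sampling of
√(vx²+vy²)), and the reference area is c per unit span. In forward flight
C_D = Fx/(½ρV_mag²c) with +x the flight direction, so positive C_D is
thrust and negative C_D net drag. In hovering the reported drag uses the
resistive convention — the force component opposing the instantaneous
translation, sign-folded per half-stroke — so resistive drag averages to a
positive number; at the stroke reversals (zero speed) the resistive C_D is
defined as zero. Static configurations (no kinematics) normalize by V∞.

## Wing sections

All four study sections share c = 4 mm and mid-chord pitch reference:

* **Corrugated (bee-like stand-in).** A real bee wing cut is not
  distributable, so a parametric generator emulates its salient structure: a
  camber line interpolated through n = 8 vein nodes with alternating ±0.02c
  offsets, a membrane of 0.0125c offset half-thickness along the camber
  normal, circular vein thickenings of radius 0.0125c at the nodes, and a
  camber indentation at 0.55c (the fore/hind interface), its depth scaling
  with the corrugation amplitude so the zero-corrugation limit degenerates
  exactly to the flat plate. Optional seeded jitter perturbs the node
  positions; the default is deterministic. The generator emits one connected
  loop (whether the real fore and hind sections touch at the interface or
  are bridged by the humuli is not resolvable here; the file format and the
  solver accept multi-loop sections).
* **Approximate.** The corrugated section low-passed with a 0.2c window —
  the smoothed counterpart that tests whether vein-scale relief matters.
* **Ellipse** of 0.125c maximum thickness and **flat plate** of 0.0125c
  uniform thickness with semicircular caps — the two idealizations common in
  the literature.

The smoothing operator decomposes the boundary into camber and thickness
distributions on fixed interior stations, replaces each by its
discrete-cosine expansion with wavelengths ≥ 2·window passed untouched and
a raised-cosine roll-off down to the window scale, and rebuilds the section
with analytically rounded caps. Because resolved scales pass exactly, the
operation is idempotent on already-smooth profiles (verified to 10⁻⁹·c);
an amplitude guard rescales the filtered camber if spectral end effects
would exceed the input's relief. The window argument is in mm and must be
smaller than the chord.

## Packaged studies and presets

* `validation` — the hovering-plate benchmark: flat plate, c = 23.85 mm, in
  mineral oil (ρ = 880 kg/m³, ν = 1.15×10⁻⁴ m²/s), closed tank, f = 0.25 Hz,
  r0 = 0.1625 m, θ1A = 23.5°, θ3A = 45°, four cycles from rest, statistics
  over the final cycle. Reference cycle-averaged values: C_L ≈ 0.82,
  resistive C_D ≈ 1.33 (the matched experiment reported 0.86/1.34).
* `section-sweep` — the four sections under forward-flight kinematics
  across 1–5 m/s in standard air (ρ = 1.204 kg/m³, μ = 1.82×10⁻⁵ Pa·s —
  the study's fluid is unstated, so sea-level values are adopted), compared
  by cycle means and RMSD against the corrugated reference over a shared
  τ window resampled to a uniform grid (canonically 1600 points on
  τ ∈ [3, 15); the coarse preset uses τ ∈ [2, 4)).

Presets: `coarse` = 256² tank (4 cycles) / 384×192 forward domain
(3 cycles, statistics over τ ∈ [1, 3)) — the test surface, sized for
minutes-per-case on one CPU (the forward grid is the coarsest that resolves
the low-speed thrust–drag balance; at 256×128 the 1 m/s cases sit on the
wrong side of zero mean C_D); `paper-like` = 512² / 512×256, 15 cycles,
statistics over τ ∈ [3, 15) — the faithful mode, hours-per-case.

Choices the sources leave open, fixed here once:

* **Tank size** 0.30 m × 0.30 m (~12.6 chords; the stroke spans 0.133 m
  peak-to-peak). Lift in a closed 2D tank depends mildly on this choice.
* **Validation plate thickness** 0.10c: the literature's 0.0125c plate is
  far below one cell at tank resolutions; 0.10c spans ≥ 2 cells. Thickness
  sensitivity measured at 128²: C_L 0.27 / 0.37 / 0.40 at 0.05c/0.10c/0.15c.
* **Validation pitch axis** at quarter-chord from the leading edge (robotic
  hovering rigs pitch their wings about an axis near the leading edge);
  the four-section comparison keeps mid-chord so the sections stay
  geometrically comparable.

## Verification and validation summary

Everything below is computed by the test suite at the stated sizes.

* Taylor–Green vortex, 256², ν = 2×10⁻³: kinetic energy follows
  exp(−4νk²t) to better than 1%.
* Observed spatial convergence order between 64² and 128² against the
  analytic Taylor–Green solution: ≥ 1.9 (measured ≈ 3 at these sizes, the
  asymptotic order is 2).
* Penalized-slab Couette channel: linear shear profile within 2% at 64².
* In-solid velocity mismatch halves when η halves (stiff regime).
* Static body in a freestream vs the same body towed quasi-steadily through
  still fluid: drag agrees within 10% (Galilean consistency of the
  penalized force).
* Newton's third law: in a periodic box the fluid's momentum gain equals
  the body's accumulated impulse within 5%.
* Hovering benchmark at the coarse preset: resistive C_D = 1.45, within
  10% of the reference 1.33. The lift coefficient converges from below —
  final-cycle C_L 0.51 at 128², 0.56 at 256² — and sits ~30% under the
  reference 0.82 at 256². The deficit is the
  expected behaviour of a diffuse-interface method at ~20 cells per chord:
  drag is bluff-body pressure drag and converges quickly, while lift rides
  on the leading-edge suction peak, which the smeared interface
  under-resolves. Two further effects compound at desk scale: the lift
  decays cycle-over-cycle (0.63 → 0.52 over four cycles at 128²) as the
  wing descends into its own accumulated downwash — a known feature of 2D
  hovering in confined domains, making the final-cycle average conservative
  — and the benchmark's tank size, plate thickness, pitch axis and
  averaging window are not published, each worth several percent. The
  reference value was produced by a body-fitted moving-mesh solver at ≥506k
  cells, eight times this preset's cell count.

## What the synthetic data do and do not show

The corrugated generator reproduces the *kind* of geometric relief a real
bee section has — thin membrane, discrete vein bumps, an interface notch —
not its actual shape: passing comparisons between the corrugated and
simplified sections demonstrate that the pipeline resolves
cross-section-dependent aerodynamics, not that any number matches a
particular insect. Similarly, at coarse presets the effective Reynolds
number is reduced by discretization, so qualitative structure (vortex-street
topology, thrust–drag transition, per-cycle peak counts) is meaningful while
absolute forward-flight coefficients are not grid-converged.

## Known limitations

* 2D only; no spanwise flow, no wing flexibility, no stroke-plane deviation
  beyond the two translation axes, no fluid–structure interaction.
* The penalized interface is diffuse at one cell; sharp-edge suction is
  under-resolved at coarse grids (see the lift discussion above).
* The closed-tank hovering problem has no statistically steady state in 2D;
  cycle averages depend on the averaging window.
* Force histories carry small step-scale chatter as the moving mask crosses
  cell boundaries; statistics are computed on the τ-resampled traces.
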