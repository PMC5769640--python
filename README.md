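# wingflow

2D unsteady aerodynamics of flapping insect wing cross-sections.

Insect-scale flapping flight is carried by unsteady vortex mechanics — above
all the leading-edge vortex (LEV) that forms and sheds on every half-stroke.
Most computational studies idealize the wing cross-section as a flat plate or
an ellipse, but a real bee wing cut is a thin, pleated membrane with discrete
vein thickenings and an interface notch where the fore and hind wings couple.
`wingflow` is a library for asking how much that cross-sectional morphology
matters: it simulates prescribed bee-like flapping of interchangeable 2D
sections and compares the resulting force histories.

The package is aimed at researchers in computational biomechanics and
micro-air-vehicle aerodynamics who want a fully scripted, dependency-light
pipeline: geometry in, force coefficients and comparison statistics out.

## What is inside

* **`wingflow.profiles`** — wing-section geometry: a parametric corrugated
  (bee-like) generator, its low-pass "approximate" counterpart, ellipse and
  flat-plate sections, solid-fraction rasterization, and a plain-text polygon
  file format.
* **`wingflow.kinematics`** — the flapping motion. Forward flight renders the
  3D wing path (yaw, roll, pitch about the wing base) as planar translations
  of the section at pivot radius r0 plus a pitch angle:

      x(t)   = r0 θ1A cos(ω t),   y(t) = r0 θ2A cos(ω t + φ2),
      θ3(t)  = θ3A sin(ω t),      ω = 2π f,

  with f = 150 Hz, θ1A = 110°, θ3A = 24°, r0 = 6.61 mm and θ2A looked up per
  flight speed (10°–26° over 1–5 m/s). A hovering mode drives the
  tank-validation benchmark.
* **`wingflow.solver`** — incompressible Navier–Stokes on a fixed staggered
  Cartesian grid. The moving wing is imposed by Brinkman volume penalization
  (forcing −χ/η (u − u_body) inside the solid mask χ) and the pressure
  projection enforces ∇·u = 0 to machine precision each step. Time steps
  follow a kinematics-aware CFL rule with an explicit diffusive budget.
* **`wingflow.forces`** — the hydrodynamic force is the momentum exchanged in
  the penalization substep, normalized as

      C_L = F_y / (½ ρ V_mag² c),   C_D = F_x / (½ ρ V_mag² c),

  with V_mag the wing's peak translational speed. Positive C_D is thrust in
  forward flight; hovering uses the resistive convention (drag opposes the
  instantaneous motion, folded per half-stroke).
* **`wingflow.analysis`** — cycle averages on a uniform stroke-phase grid,
  root-mean-square differences between sections,
  RMSD = sqrt(1/n Σ (a_i − ref_i)²), and lift-peak counting.
* **`wingflow.workbench`** — packaged studies (`validation`,
  `section-sweep`), resolution presets, fixtures, YAML case configs, a
  domain-width sweep, plus a thin `wingflow` command-line interface.

## A worked example

`examples/04_hovering_plate_validation.py` runs the benchmark that anchors
the solver: a flat plate (chord 23.85 mm) swept sinusoidally through still
mineral oil (ρ = 880 kg/m³, ν = 1.15×10⁻⁴ m²/s) in a closed tank at
f = 0.25 Hz, stroke amplitude 23.5° at pivot radius 0.1625 m, pitching 45°
from vertical at mid-stroke. On the reduced 96² example grid it prints:

```
grid 96x96, 4 cycles, window tau in [3.0, 4.0)
mean C_L = 0.521   (benchmark ~0.82; grid-limited here)
mean C_D = 1.556   (benchmark ~1.33, resistive convention)
```

The drag coefficient — bluff-body pressure drag — lands within ~10% of the
benchmark once the preset 256² tank grid is used; the lift coefficient is
carried by leading-edge-vortex circulation and converges from below as the
grid is refined (see `docs/methods.md` for the resolution study and its
limits).

The other examples build the four wing sections, trace the forward-flight
kinematics, verify the solver against the decaying Taylor–Green vortex, and
compare sections under identical kinematics:

```bash
python examples/01_wing_sections.py
python examples/05_section_comparison.py
```

The CLI wraps the same library calls:

```bash
wingflow run validation --preset coarse --out out/
wingflow run section-sweep --sections plate,ellipse --speeds 1,5 --out out/
wingflow fixtures profiles
```

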