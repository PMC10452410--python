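# Methods

`periflow` models how blood and a model plasma protein (fibrinogen) are
recruited into the gap between a screw-shaped dental implant and the
surrounding bone socket during the first seconds after placement, and how
three implant surface topographies — amorphous, nano-trabecular, and a
hybrid of meso-scale spikes with nano-trabeculae — change that
recruitment.  This note records the model, its assumptions, the default
parameters and why they hold their values, what the synthetic benchmark
cases do and do not validate, and the package's known limitations.

## 1. Geometry and zones

The domain is a two-dimensional axial half cross-section: lateral
coordinate `x` from the implant axis outward, vertical coordinate `y`
positive upward (toward the outlet).  A 2D section was chosen because the
quantities of interest (zone-resolved densities, vector components,
recruitment ratios) are cross-sectional reductions, and a resolved 3D
helical-thread domain is not a desk-scale computation.  The half-domain
uses symmetry at the implant axis.

The implant profile is, from the apex upward: a flat apex at the thread
core half-width, `thread_count` triangular thread ridges (depth 0.35 mm,
pitch 1.2 mm — typical commercial screw values; both configurable)
reaching the full 2 mm half-width, then a smooth collar.  Default
dimensions are 11 mm length, 4 mm diameter, 3 threads, and a 0.3 mm
implant–bone gap.  The bone socket is a vertical solid wall 0.3 mm outside
the widest implant radius.  Blood enters through the whole bottom boundary
(apex inlet) and through a 1 mm patch of the bone wall between 0.7 and
1.7 mm height (side-wall inlet); the only outlet is the gap opening at the
top.  The domain is rasterized onto a uniform structured grid
(cell-centred scalars, face-centred velocities; 0-based indices).

Every fluid cell carries exactly one zone label:

* **interface** — fluid within `interface_thickness` of the implant
  surface (default 100 µm, one-third of the gap; the value is not
  derivable from the physical setup, and one-third of the gap keeps the band
  at least four cells wide at the default resolution);
* **thread** — fluid inside the thread envelope (between the core and the
  crest line, vertically from the first thread crest to the collar
  shoulder) that is not interface.  With three ridges this yields exactly
  three disjoint pockets;
* **outer** — all remaining fluid.

## 2. Surface texture

Texture enters at three levels:

* **Height maps** (`generate_texture_heightmap`) are the synthetic analog
  of areal profilometry: crisscrossed triangular spikes (40 µm
  peak-to-valley, 50 µm period) for the meso scale, touching
  cosine-squared nodules (300 nm peak-to-valley and width) for the nano
  scale, superposed for the hybrid surface.  Waveforms are phase-aligned
  to the sample lattice so the nominal peak-to-valley amplitude is
  represented exactly whenever the sample spacing divides the feature
  period.  Roughness parameters follow the areal (ISO 25178-style)
  definitions: Sa is the mean absolute deviation from the mean plane, Sz
  the maximum peak height plus pit depth, and Sdr the extra surface area
  from the texture relative to the planar area (triangulated facet
  summation).  Sdr is reported both as a dimensionless fraction and as a
  percentage.
* **Geometric serration** (`apply_texture_to_profile`): where the grid
  resolves the spikes (h ≤ spike width / 4), the meso sawtooth is carved
  into the profile along the boundary normal.  Laser texturing removes
  material, so the carving is inward and the spike peaks stay flush with
  the nominal surface.
* **Sub-grid models**: at the default 25 µm grid the 50 µm spikes and the
  300 nm nodules are below resolution, so they enter the flow solver as
  (a) a Wenzel effective contact angle and (b) a porous drag/wicking layer
  (next section).

The Wenzel roughness ratio r = 1 + Sdr is computed from the generated
height maps of whichever scales the grid does not resolve; hierarchical
scales compose multiplicatively.  With the defaults, r ≈ 2.0 for the nano
texture and r ≈ 3.0 for the hybrid texture, giving effective contact
angles of ≈ 47° (nano) and 0° (hybrid, clamped) from the 70° base angle.

## 3. Two-phase flow

One-fluid volume-of-fluid (VOF) formulation on a staggered MAC grid.  The
liquid is a single Newtonian phase ("blood"); the initial gap content is a
void gas phase.  The reported "plasma density" is the liquid volume
fraction α, and "whole blood" velocities are the one-fluid velocities —
both derive from the same flow solution.

Each step: (1) dimensionally split conservative advection of α with a
compressive MUSCL/superbee flux and a divergence correction using the
start-of-step liquid indicator, so the correction telescopes to the exact
cell divergence over the step; (2) explicit momentum predictor with upwind
advection, variable density/viscosity (arithmetic α-mixtures),
continuum-surface-force (CSF) surface tension with smoothed curvature, the
wetting forces below, optional gravity (off by default — the filling is
inlet- and capillarity-driven and the orientation of the socket is not
part of the model), and implicit per-face Darcy drag; (3) variable-
coefficient pressure projection (ILU-preconditioned BiCGSTAB, relative
tolerance 1e-8) to the prescribed divergence; (4) boundary conditions
(prescribed inlet speed with α = 1, no-slip walls, zero-gradient outlet at
reference pressure, symmetry slip at the axis).

The time step is the minimum of the advective CFL bound (default CFL
0.4), the explicit viscous bound 0.2 h²/ν, the explicit capillary bound
√(ρ̄h³/2πσ), and `dt_max`.

### Wetting

Two capillary wall terms act on the sharp α-gradient at faces:

* **Contact-line (Young) force.**  Wetting a unit area of wall releases
  σ cos θ_eff of interfacial energy, so the contact line is pulled toward
  the dry side with that force per unit wetted width, localized over the
  one-cell wall band.  Its integral across a channel reproduces the
  Laplace driving pressure 2σ cos θ/W exactly, independent of how well the
  smoothed-curvature CSF resolves the meniscus; the CSF term supplies the
  dynamic resistance.  This formulation was chosen over rotating the
  interface normal at wall cells because, at the coarse resolutions used
  here, the normal-rotation approach recovered only a small fraction of
  the equilibrium capillary pressure in the plate-imbibition benchmark,
  while the energy-based force reproduces Lucas–Washburn penetration to
  within a few tens of percent.
* **Texture wicking.**  Where the meso spikes are unresolved, the spike
  layer (one spike height thick along the implant surface) exerts a
  capillary suction 4σ cos θ_pore / w_spike on faces whose drier cell lies
  in the layer — the layer draws liquid in but never ejects it.  The
  pore-scale wetting angle θ_pore is Wenzel-corrected by the nano
  roughness ratio, because the spike walls themselves carry the
  nano-nodules.

### Sub-grid spike drag

The unresolved spike layer is treated as a porous medium with
Carman–Kozeny-type permeability K = w²/360 (porosity ≈ 0.5, feature size
= spike width).  The Darcy coefficient μ(α)/(ρ(α)K) is phase-dependent:
the viscous liquid is strongly retained inside the layer while the thin
gas it displaces leaves the pores with little resistance.  (An early
formulation applied the liquid-strength drag to both phases; it trapped a
permanent gas film against the textured surface — the layer could never
admit the liquid — which is unphysical for a gas ~70× less viscous than
plasma.)  The drag enters both the momentum update (implicitly, per face)
and the projection coefficients.  For nano-only textures represented as
`drag_layer`, the nodules merely displace the effective no-slip plane by
their 300 nm height — deliberately almost a no-op at domain-scale grids.

### Trapped-gas venting

In a 2D cross-section the thread bays seal and trap gas that, in the real
3D helical geometry, escapes out of plane; a strictly incompressible
projection would therefore never let the bays fill.  Enclosed gas pockets
(gas regions with no connected path to an outlet, recomputed every 10
steps) receive a volumetric sink, div u = −k_vent (1 − α), representing
the out-of-plane escape.  Gas inside the unresolved spike layer vents
unconditionally and at a faster rate (`layer_vent_rate`, default 5 s⁻¹,
fast relative to the fill transient): the spike valleys are open channels
out of the section plane, so the layer cannot hold any stable in-plane
gas content — without this, an artificial gas film clings to the textured
surface because its only in-plane escape path runs along the thin
resistive layer itself.  The (1 − α) factor makes both sinks
self-limiting.  Cells carrying an active vent sink are excluded from the
advection scheme's liquid indicator so the vented volume is charged to
the gas phase, never to the liquid; liquid cells remain divergence-free
to the solver tolerance and the liquid mass ledger is unaffected.  The
bay vent rate is part of the fill-sequence calibration below.

## 4. Fibrinogen transport

Fibrinogen is a passive scalar carried by the liquid: concentration c
normalized to the inlet value, conserved quantity m = cα.  m is advected
inside the same flux sweeps as α with upwind face concentrations, which
makes c ≡ 1 throughout the liquid an exact fixed point and keeps c
carrier-limited and bounded (a discrete maximum principle).  Diffusion
(default D = 2×10⁻¹¹ m²/s, literature scale for a ~340 kDa protein) is
operator-split and batched while the accumulated diffusion number is far
below the stability bound — on the 3 s fill transient the diffusion
length is ~11 µm, below one cell.  No adsorption or surface binding is
modelled (recruitment, not binding); this is an extension point.

## 5. Fluid properties and the desk-scale set

`FluidProperties()` defaults are physiological: plasma ρ = 1025 kg/m³,
μ = 1.4 mPa·s; air ρ = 1.2 kg/m³, μ = 1.8×10⁻⁵ Pa·s; σ = 0.058 N/m; base
contact angle 70°.

The coarse implant experiment cannot run with the physiological σ: the
explicit capillary time-step bound at h = 25 µm is ≈ 5 µs, i.e. ~6×10⁵
steps for one 3 s transient.  The documented desk-scale set
(`FluidProperties.desk_scale()`, also the config-file default) therefore
scales σ to 1×10⁻⁴ N/m and raises the gas density to 20 kg/m³ (gas
kinematic viscosity would otherwise bind the viscous step limit), which
puts the capillary, viscous and advective bounds in the same ~1×10⁻⁴ s
range (~3.3×10⁴ steps per run).  Consequences: the capillary number is
~100× larger than physiological, so wetting contrasts between topographies
are weaker than they would be in reality (sub-millisecond real spike
wicking becomes ~0.1 s here), and the density ratio is 51 rather than
854.  Topography contrasts survive the scaling because all three surfaces
share the same scaled fluids and differ only in wetting/drag.

## 6. Fill-sequence calibration

The inlet speed and vent rate are not derivable from first principles;
they are fixed once, using the amorphous run, so that the default
experiment exhibits its intended fill scenario, and are then frozen for
all topographies:

1. the open (outer) region completes filling just before 3 s — with
   ~5.8 mm² of fluid area and 3.3 mm of inlet span this puts the inlet
   speed at 0.65 mm/s (fill time ≈ 2.7 s);
2. voids persist in the thread bays and at the interface at 1 s and are
   still resolving at 3 s, most visibly around the amorphous surface —
   the bay vent rate 0.3 s⁻¹ clears a sealed pocket with a ~3 s time
   constant after sealing, so infiltration is still progressing through
   the whole 1–3 s window rather than completing abruptly.

The calibration targets the fill *sequence* (where voids are at 1 s and
how far filling has progressed at 3 s), not the cross-topography ratios
that are the experiment's outputs; those emerge from the wetting and
drag models.

## 7. Zone metrics and the comparison summary

Zone reductions are liquid-weighted by default (the blood phase carries
the quantities of interest); unweighted means are available by flag.
Per-zone outputs: liquid fraction; species mass Σ cα·cell-area (reported
in mm² of inlet-normalized concentration); mean velocity as (vertical,
horizontal) components with *up* = toward the outlet and *in* = toward the
implant axis positive; speed = |mean vector| ("total velocity combined
from the components"), with the mean of cell-speed magnitudes kept as a
secondary column.  A zone holding essentially no liquid reports NaN (the
average is undefined, not zero).  Recruitment totals sum interface +
thread at the end time; recruitment efficiency is the interface quantity
as a percentage of the thread quantity.

The qualitative summary table maps ratios-to-amorphous onto labels with
documented, configurable thresholds: ≥ 1.5 → "++", ≥ 1.15 → "+", ≤ 0.85 →
"−", else "+/−"; speeds use the inverted sense ("Very slow" below 1/1.5,
"Slow" below 1/1.15); direction words come from the signs of the mean
components.

## 8. Benchmarks: what they show

* **poiseuille** — body-force plane channel against the parabolic closed
  form (L2 error < 2% at 32 cells, observed order ≥ 1): viscous terms,
  no-slip walls, and the projection in single-phase flow.
* **static_droplet** — Young–Laplace jump σ/R within 10% at 64²: CSF
  surface tension and the two-phase projection.
* **gaussian_diffusion** — point-release second moment 4Dt within 2%:
  the species diffusion operator (the discrete FTCS moment growth is
  exact, so the error is dominated by boundary truncation).
* **capillary_channel** — plate imbibition against Lucas–Washburn: the
  contact-line force.  The solver under-predicts the closed form by a few
  tens of percent (dynamic contact-line resistance and inertia that
  Lucas–Washburn neglects), so the benchmark asserts the √t growth and a
  factor-two envelope rather than a tight tolerance.
* **mini_implant** — the full coarse pipeline on a short transient; its
  error metric is the liquid mass-balance defect.

Every benchmark generates its own inputs and runs in minutes on one CPU.
Passing them validates the discrete operators against closed forms; it
does not validate the sub-grid texture models against real textured
surfaces, for which no closed form exists — those carry the model
assumptions stated above.

## 9. Determinism and numerical bookkeeping

All computations are deterministic: fixed iteration orders, seeded (and by
default absent) stochastic texture jitter, and a deterministic linear
solver; two runs of the same configuration produce bit-identical zone
series.  Liquid and species budgets are tracked exactly as the sum of
boundary fluxes from the advection sweeps, inlet Dirichlet top-ups, and
[0,1]-clipping corrections; the residual mass-balance error on the default
runs is O(10⁻⁴) against a 1% acceptance bound.  VOF boundedness is
enforced to 1e-8.  Checkpoint and series times are hit exactly by
shortening the step.  Degenerate inputs (empty zones, zero thread
quantity, dry zones) raise typed errors rather than returning silent
zeros.

## 10. Known limitations

* 2D cross-section: no helical transport, and trapped-gas venting is a
  model for out-of-plane escape, not a resolved mechanism.
* Desk-scale fluid set: weaker capillary contrasts than physiological
  (section 5); results are read as orderings and ratios, not absolute
  speeds.
* Newtonian single-phase blood; no cells, no coagulation, no adsorption.
* The spike layer's porous parameters (porosity 0.5, K = w²/360) are
  dimensional estimates, not fits to resolved spike-scale simulations.
* First-order upwind momentum advection: acceptable at the fill
  transient's Reynolds numbers (Re ~ 1), diffusive at higher Re.
* No blood/protein time lag: liquid enters carrying the full inlet
  fibrinogen concentration, so c ≈ 1 throughout the liquid and the
  cross-topography fibrinogen ratios track the plasma ratios instead of
  amplifying them.  A lag would need an explicit mechanism (delayed
  protein release, adsorption, or dispersion) that the advection-diffusion
  model deliberately does not include.
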