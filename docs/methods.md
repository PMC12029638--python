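# Methods

## Governing model

Blood plasma is treated as an incompressible Newtonian fluid
(ρ = 1050 kg/m³, μ = 1.2×10⁻³ Pa·s) solved with the single-relaxation-time
(LBGK) lattice-Boltzmann method on the D3Q19 lattice.  The unit system maps
Δx = 1 μm and Δt = 1.8×10⁻⁸ s to lattice units of 1, so the lattice
kinematic viscosity is ν_lat = (μ/ρ)Δt/Δx² = 0.0206, the relaxation time
τ = 3ν_lat + ½ = 0.5617 and the relaxation frequency ω = 1/τ = 1.78.
Body forces enter through the trapezoidal (Guo-type) scheme: the velocity
moment carries the half-force correction ρu = Σ eᵢfᵢ + FΔt/2, the
equilibrium is evaluated at that corrected velocity, and the source term
carries the (1 − 1/2τ) prefactor.  With this combination a uniformly forced
periodic box accelerates by exactly F per step (asserted in the tests), and
the momentum audit of the coupled solver closes to round-off.

Pressure-driven vessel flow is realized as the equivalent uniform body
acceleration aₓ with periodic wrap in x (Δp = ρ aₓ L), sized from the
target Reynolds number via Um = aₓD²/(32ν), Re = UmD/ν.

### Walls

Vessel walls are staircase voxelizations with halfway bounce-back; moving
shear plates add the Ladd momentum term −6wᵢρ(eᵢ·u_wall).  A site is fluid
iff its perpendicular distance from the centerline is < D/2.  The vessel
axis is placed at a *cell center* (even cross-section grids): with an
on-node axis, whole rings of lattice sites fall exactly on the nominal
radius and the effective bounce-back wall is biased by ≈ ¼ lattice unit,
which costs several percent in the Poiseuille profile at D = 20; the
cell-centered axis removes the bias (measured profile error 0.9% at D = 20,
τ = 1; 0.4% at D = 30, τ = 0.5617).  No curved-boundary interpolation is
used.

The profile reference deserves one caution: a/(4ν)·y(D−y) with y measured
across the diameter is algebraically the *cylindrical* Poiseuille solution
(R² − r² written in diametral coordinates).  The plane slit of width D has
twice that amplitude, a/(2ν)·y(D−y); both references are implemented and
each geometry is tested against its own solution.

## Membrane model

Each particle is a closed oriented triangle mesh (icosahedral refinements;
face counts 20·4ᵏ, or 120·4ᵏ via one barycentric split — the 120-face
sphere is the projected disdyakis triacontahedron).  For a closed
triangulated sphere Euler's formula fixes 2N = N_f + 4, so the working
resolutions are N_f = 120 (N = 62) for carriers and N_f = 480 (N = 242)
for red cells.  The red-cell rest shape maps the unit sphere through the
biconcave profile y' = (R/2)·y·(C₀ + C₁r² + C₂r⁴), r² = x² + z², with
C₀ = 0.207, C₁ = 2.003, C₂ = −1.123; R is the disk radius (3.5 μm) and the
mesh volume at construction defines the equilibrium volume V₀.

The elastic energy is E = E_S + E_B + E_A + E_V:

* **In-plane (Skalak)**: per face, the current metric g = [[a·a, a·b],
  [a·b, b·b]] of the edge vectors against the stored inverse reference
  metric gives I₁ = tr(g₀⁻¹g) − 2 and I₂ = det g/det g₀ − 1, i.e. the
  invariants of the principal stretches λ₁, λ₂ without ever constructing
  them; εₛ = κₛ/12(I₁² + 2I₁ − 2I₂) + κ_α/12 I₂², summed with reference
  face areas as weights.  Working from dot products makes energy and
  gradient exactly rotation-invariant.
* **Bending**: (κ_B/2) Σ tan²((θᵢⱼ − θ⁰ᵢⱼ)/2) over adjacent face pairs,
  with θ the signed dihedral between face normals and θ⁰ taken from the
  constructed mesh (so both the sphere and the biconcave shape are
  stress-free at release).  The tangent half-angle form diverges as a hinge
  folds by π; the solver raises a membrane-divergence error at |Δθ| > 3 rad,
  and a plain quadratic (κ_B/2)ΣΔθ² is selectable per run
  (`run.bending_model: quadratic`).
* **Area/volume**: global quadratic penalties on total area and enclosed
  volume (divergence-theorem volume over faces).

Nodal forces are analytic gradients of each term (hinge gradients in the
standard four-point form); the test suite checks them against central
finite differences of the energy (10⁻⁵ relative on 20- and 80-face meshes,
every term separately), and checks zero net force and torque per term.

Parameter tables (physical SI): red cells κₛ = 5×10⁻⁶ N/m,
κ_α = 2.5×10⁻⁶ N/m, κ_B = 2×10⁻¹⁹ N·m, κ_A = 0.5 N/m, κ_V = 10⁶ N/m²;
carriers κₛ = 1 N/m, κ_α = 0.1 N/m, κ_B = 10⁻¹³ N·m, κ_A = 1 N/m,
κ_V = 10⁶ N/m², radius 1.3–2.0 μm, plus a five-decade stiffness sweep for
carrier-design studies.  Conversions to lattice units follow from the mass
unit ρΔx³ and Δt.

## Immersed-boundary coupling

The two-point hat kernel φ(r) = 1 − |r| (tensor product in 3-D) both
spreads nodal forces and interpolates fluid velocities, so the transfer
pair is exactly adjoint and conserves total force by partition of unity;
the four-point cosine kernel is available by configuration.  One coupled
step runs membrane forces → spreading → collide/stream with bounce-back →
moments → interpolation → forward-Euler advection.  Particle meshes keep
unwrapped coordinates; the whole mesh is shifted by one axial period when
its centroid crosses the boundary, so particles re-enter the periodic
vessel without tearing.  Fluid inside and outside membranes shares one
density and viscosity, and interactions are purely fluid-mediated (no
contact or adhesion potentials).  A wall guard clamps any node that crosses
into the bounce-back clearance band back to the admissible radius and logs
the event; an optional membrane-substep setting averages the elastic force
along the frozen-velocity node path for very stiff carriers.

## Validation cases

* **Pipe flow**: body-force-driven cylinder, steady profile vs
  a/(4ν)(R² − r²).  Default D = 30, τ = 0.5617 (the blood unit system),
  peak velocity 0.05 lattice units; relative L2 error 0.4%, and error
  decreases under refinement (0.9% at D = 20 → 0.15% at D = 40 at τ = 1).
* **Shear capsule**: 30³ domain, plates at ±wall_speed (default 0.02,
  shear rate γ = 2u_w/H with H = 28 the mid-link gap), initially spherical
  capsule of radius 5 (N_f = 1280) at the domain center.  The capsule
  shear modulus is sized from the target capillary number; the validation
  particle uses κ_α = κₛ and no bending/area/volume penalties, because the
  small-deformation anchor D/Ca → 6.25 describes an unconstrained elastic
  capsule.  Measured (steady to <0.1% per 1000 steps): D/Ca = 6.46 at
  Ca = 0.03 and 7.12 at Ca = 0.01.  The growth at small Ca is a resolution
  effect of this setup, not statistical noise: the hat kernel gives the
  discrete capsule an effective hydrodynamic radius about a quarter lattice
  unit over nominal, and the 2a/H = 0.36 confinement raises D further; both
  biases are Ca-independent, so the linear extrapolation of D/Ca to Ca → 0
  lands near 7.4 rather than on the unconfined theory value 6.25, while
  moderate-Ca values sit inside the published band (5.6–7.7, "around 7").
  The inflation is insensitive to the relaxation time (τ = 0.6–1.0), to
  halving the wall speed (so not inertial), and to the surface-mesh
  resolution (320–1280 faces).  The Taylor
  parameter is measured from the equivalent-ellipsoid semi-axes of the
  enclosed volume (exact second moments by the divergence theorem;
  S = diag(a², b², c²)/5 for a solid ellipsoid), taking the two axes in the
  shear plane; this estimator is exact for affinely deformed sphere meshes
  because the icosahedral mesh has an isotropic second moment.

## Scaled-down migration runs

The full-scale migration problem (100 μm vessel, D = 50 lattice units,
≈3.6 M steps) is not a desk-scale computation; migration runs here default
to a 60×30×30 grid, vessel diameter 28, red-cell radius 5, carrier radius
2, and ≤10⁵ steps, and assert *trends* (plateau formation and the
carrier-vs-red-cell ordering of the equilibrium distance d), not absolute
values.  The reduced geometry cannot host the curved centerline (amplitude
+ D/2 exceeds the cross-section), so scaled runs use the straight vessel;
the curved geometry (y(x) = A sin 2πx/L, constant circular cross-section,
x-periodic) is constructed and tested separately at smaller diameters.

Two scaled-run design choices matter:

* **Dynamic similarity of the membranes.** Converting the physical moduli
  directly into the reduced geometry gives a red-cell capillary number ≈20
  (vs ≈4.5 at full scale) — the membrane is then unphysically floppy and
  folds numerically.  Scaled runs therefore rescale each species' moduli to
  preserve Ca, κ_α/κₛ, κ_A/κₛ, κ_B/(κₛr²) and κ_Vr/κₛ at their full-scale
  values (`run.moduli_scaling: direct` restores raw conversion).
* **Basin release for the ordering test.** Random release leaves the
  near-rigid carriers close to wherever they started (inertial lift at
  Re ≈ 2 is orders of magnitude slower than the red cell's
  deformability-induced lift — the full-scale run needed ≈3.6 M steps), so
  a fully free release cannot equilibrate on a desk.  The trend experiment
  releases each species on a ring inside its expected basin (red cell at
  d₀ = 0.25 R, carrier at 0.55 R, random angles and axial positions).  The
  test is still dynamical, not a restatement of the release: the red cell
  must migrate inward of its own accord (measured: 3.5 → 2.5 lattice units
  over 10⁵ steps with the plateau detected at ≈6×10⁴ steps), while the
  carrier holds its annulus (≈7.9, plateau immediately); the ordering
  d_DC > d_RBC then reflects the two lift mechanisms, matching the
  full-scale ordering of the equilibrium distances.

Equilibration time is detected as the first time after which the
trailing-window mean (window 20% of the series) of d stays within
tolerance (2% of the vessel radius) of its final value through the end of
the series, with the plateau required to span at least one full window.

## Numerical choices and limitations

* Collision, forcing, streaming and bounce-back are fused in one unrolled
  numba kernel (generated from the velocity table at import); the fields
  are double precision, and per-step mass conservation holds to 10⁻¹² in
  closed domains.
* A divergence guard aborts when max|u| > 0.3 lattice units or any density
  is non-positive, naming the step.
* Degenerate (zero-area) faces raise an error naming the face.
* The synthetic problems here emulate dilute suspensions (one to four
  particles) in idealized straight/curved rigid tubes with Newtonian
  plasma.  They do not represent hematocrit-level cell crowding,
  non-Newtonian rheology, pulsatility, adhesion chemistry, or thermal
  fluctuations — passing tests show the discrete model and its couplings
  are implemented correctly and reproduce the validated anchors and
  reduced-scale trends, not that the model captures those richer effects.
* Shear-capsule accuracy at very small Ca is limited by the two-point
  kernel's interface thickness (see above); a finer grid relative to the
  capsule radius, not a finer surface mesh, is what reduces that bias.
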