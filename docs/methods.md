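# Methods

`venavalve` simulates the interaction of venous blood with a bicuspid
venous valve in a straight vein segment, using the immersed-boundary
method with a finite-element description of the tissue (IB/FE). This
note records the model, the numerical choices, and what the desk-scale
configurations do and do not demonstrate.

## Model

**Frames and coupling.** The blood occupies a fixed Cartesian box
(Eulerian frame); the vein wall, sinus and leaflets are an elastic body
tracked by material coordinates (Lagrangian frame). The two are coupled
through a regularised delta function: tissue elastic force densities are
*spread* onto the fluid grid, and tissue points *move with* the locally
interpolated fluid velocity. The fluid obeys the incompressible
Navier–Stokes equations with uniform density ρ = 1.08 g/cm³ and
viscosity μ = 0.36 P (0.036 Pa·s); the no-slip condition on the tissue
and the tissue's incompressibility are consequences of the coupling, not
separate constraints.

**Elasticity.** Tissue stresses derive from isotropic, nearly
incompressible strain energies of the deformation gradient F
(I₁ = tr FᵀF, I₃ = det FᵀF):

* leaflets (polynomial): Ψ = c₀(I₁−3) + c₁(I₁−3)² + (β/4)log²I₃ with
  c₀ = 4 kPa, c₁ = 170.06;
* wall (exponential): Ψ = c₂(exp[c₃(I₁−3)²]−1) + (β/4)log²I₃ with
  c₂ = 2.00 kPa, c₃ = 187.5;
* sinus: same exponential form at lower stiffness, c₂ = 0.50 kPa,
  c₃ = 46.875.

β = 500 kPa penalises volume change. The first Piola–Kirchhoff stress is
the energy gradient plus a correction proportional to F^{-T} that makes
P(F = I) = 0 exactly (and P(R) = 0 for rotations); this correction is
known to suppress spurious volume loss across the immersed interface.
Note the exponential form has *zero* tangent shear stiffness at the
reference state — the tissue only stiffens at finite strain — which
shapes much of the numerical behaviour below. Fibre reinforcement,
viscoelasticity and active tone are not modelled.

**Geometry.** An idealised bovine-saphenous-vein segment: luminal
diameter d = 0.691 cm, wall thickness 0.020 cm, with an axisymmetric
sinus bulge (depth 1.0 cm, thickness 0.015 cm, peak radius ratio 1.4 —
the bulge amplitude is a free parameter calibrated to the typical
anatomy) carrying two semilunar leaflets of depth 0.5 cm and thickness
0.020 cm. Leaflet attachment curves are half-ellipses in the unrolled
wall plane; free edges are straight coaptation chords (points spaced
uniformly along the chord) separated by a small gap g that initialises
the opening. The conformal tetrahedral mesh shares nodes along every
junction; the angular grid is split locally at the commissures so they
are exact wall nodes. The leaflet is meshed as a *fold of the full wall
thickness*: along the attachment row and the commissure columns its two
surface layers anchor to the inner and outer wall node layers, so no
zero-thickness elements form at the load-bearing junctions (the
commissures concentrate the valve's load, especially for stiff fibrotic
leaflets). Only the free edge collapses to a sharp midsurface row —
which keeps the coaptation gap exact — with thickness tapering over a
fixed 5·t_v length (floored at 35%) so region volumes converge under
refinement; sub-scale sliver tetrahedra left by the tapers (below 10%
of the median leaflet element volume) are dropped at build time, since
their faces are too small to exert meaningful restoring forces and they
invert under sub-cell differential motion. A penetration penalty repels
interior leaflet nodes that come within half a leaflet thickness of the
luminal wall surface, regularising the leaflet/wall squeeze film that
coarse grids cannot resolve.

**Driving protocol.** Flow is driven purely by boundary pressures: the
pressure difference Δp(t) between the distal (inlet) and proximal
(outlet) vein ends follows A·sin(2πt/T) for the first half cycle
(A = 0.5 mmHg, T = 1 s), is zero until 0.9 T, and takes a small negative
value (−0.05 mmHg, with 5 ms cosine ramps) over the last 0.1 T to seat
the valve. Both ends ride on a hydrostatic offset (4 mmHg; raised above
30 mmHg in the hypertension scenario). The end pressures act over the
vein lumen disc; the remainder of the box boundary, including the
annulus outside the vein on the end faces, is held at the zero reference
pressure, so the offset loads the wall transmurally. Disease scenarios
scale the leaflet stress-like coefficients by 10 (fibrotic) or 1/10
(atrophic).

## Numerics

* **Fluid.** Uniform MAC staggered grid (default 50×50×150 over
  1×1×3 cm). Explicit midpoint Runge–Kutta over the coupled system; a
  Chorin projection enforces incompressibility each stage. The pressure
  Poisson problem with the cell-centred Dirichlet boundary closure is
  separable on the uniform grid and is solved *exactly* by a fast
  discrete-sine-transform eigen-decomposition (periodic test mode uses
  the FFT); the post-projection divergence sits at transform round-off,
  orders of magnitude below the nominal 1e-8 tolerance.
* **Convection.** First-order upwind (advective form) by default. The
  open-boundary pressure conditions produce locally fast jets with cell
  Reynolds numbers well above the centred-scheme comfort zone, and the
  established IB codes this solver is modelled on use upwind-biased
  advection for the same reason. The second-order centred conservative
  form is available (`advection: centered`) and is used by the smooth
  low-Reynolds verification problems.
* **Structure.** Linear tetrahedra with one-point quadrature (F constant
  per element); weak-form nodal forces f_a = −V_e P ∇N_a; lumped
  reference-volume mass matrix. Thin regions carry at least one element
  through the physical thickness regardless of the in-plane resolution.
* **Coupling.** Peskin 4-point kernel by default (3-point and quintic
  B-spline 6-point available). Spreading and interpolation share one set
  of tensor-product weights per Runge–Kutta stage, so they are exact
  adjoints (power identity) and the total spread force is conserved to
  round-off.
* **Anchoring.** "Fixed" vein ends are realised as stiff penalty
  tethers over a band about one kernel support (4 cells) wide at each
  end; the spring stiffness is auto-scaled to the time step (per-node
  ω·dt ≈ 0.3), keeping end drift far below a fluid cell. A weak sponge
  (Brinkman) layer damps the exterior annulus within two cells of the
  end faces, closing the spurious leak loop around the wall edge where
  the end-face pressure steps from the lumen value to the exterior
  reference.
* **Settling.** Runs with a hydrostatic offset begin with a settling
  phase at negative time: the offset is cosine-ramped with Δp = 0 and a
  structural velocity damping (annealed to zero before t = 0) relaxes
  the wall onto its pre-stressed state without inertial overshoot
  through the zero-stiffness regime of the exponential tissue.
* **Stability.** dt must satisfy the explicit viscous bound h²ρ/(6μ)
  and the advective CFL (both checked), but in practice the binding
  constraint is elastic: the volumetric penalty acting across the
  0.02 cm tissue thickness limits dt to ≈1–2×10⁻⁵ s at desk
  resolutions, consistent with the 10⁻⁵ s used at full resolution.

## Desk-scale presets

The full-resolution configuration (`paper` preset: 50×50×150 grid,
dt = 10⁻⁵ s, three 1 s cycles ≈ 3×10⁵ steps) is a multi-hour
workstation run. Verification and the test suite use two coarse presets
(`desk16`: 16×16×48 grid with structural edge length 0.08 cm;
`desk32`: 32×32×96 with 0.05 cm) that keep the physical geometry,
tissue parameters and pressure amplitude but rescale what cannot
survive coarsening:

* **Free-edge gap g = one fluid cell** (0.0625 / 0.031 cm instead of
  0.01 cm). The gap regularises the initial coaptation; below the grid
  scale the two free edges share one kernel footprint, the fluid glues
  them together and the valve cannot open at all.
* **Cycle compressed to T = 0.25 s with the closing-dip pressure–time
  impulse preserved** (ε = 0.05·T_full/T_desk = 0.2 mmHg over the
  [0.9 T, T] window). The valve's viscous opening/closing time constants
  (set by μ, the leaflet span and the gap) do not shrink with the cycle,
  so a shorter cycle phase-shifts the response; preserving ∫Δp dt over
  the dip keeps the closure impulse the cycle delivers.
* **Hydrostatic offset 0.** At these resolutions the Lagrangian wall
  sampling (node spacing ≈ h) cannot hold a static 4 mmHg transmural
  load without percolation leaks that slowly drag the commissures; the
  offset is a common mode that does not enter the transvalvular
  dynamics the desk runs verify. The pressure–dilation response that
  the offset probes is analysed separately (below).

With these choices the desk16 preset reproduces the qualitative valve
cycle: GOA rises from the gap-limited area, plateaus, falls and reseats,
with all four phases (opening/equilibrium/closing/closed) present in the
segmentation of the final cycle, tissue volume drift below 0.01% per
cycle, and the peak transvalvular flow ordered atrophic > normal >
fibrotic across the disease scenarios. The phase *durations* at desk
scale are dominated by the coarse-grid coaptation dynamics and are not
quantitative predictions; the 15/30/20/35% split of the full-resolution
study is exercised exactly on ideal traces by the segmentation
algorithm instead.

**Pressure–dilation response.** The vein's dilation under venous
hypertension is an equilibrium property of the wall constitutive law,
so it is computed by a closed-form thin-wall analysis
(`postprocess.pressure_dilation_curve`): the Laplace balance
σ_θθ − σ_rr = Δp·r/t solved for the hoop stretch with fixed ends and
incompressible thickness change, using the package's own stress
evaluation. At 31 mmHg transmural pressure the wall parameters give
d/d0 ≈ 1.13 (strain-stiffening flattens the curve above 30 mmHg); the
softer sinus dilates substantially more. A full-FSI measurement of the
same quantity requires the fine grid.

## Observables

GOA is the ellipse-on-full-axes area π/4·D_major·D_minor of the
projected free edges (major axis commissure-to-commissure, minor axis
the largest transverse edge separation; contact within a tolerance of
g/4 counts as closed). Flow rate integrates the axial face velocities
over the lumen disc at the free-edge plane (distal→proximal positive).
The stagnant fraction is the volume fraction of the sinus pocket (the
bulge volume outside the plain lumen cylinder) below 1 cm/s. Tresca
maximum shear (σ₁−σ₃)/2 is evaluated on the Cauchy stress; the strain
measure is the largest Green–Lagrange eigenvalue. Phase segmentation
uses an absolute closed level (default: twice the reference gap area for
simulated traces; an infinitesimal level for ideal traces, which makes
the segmentation of a piecewise-linear trapezoid exact) and an
equilibrium threshold at 90% of the cycle maximum.

## Performance notes

The hot paths (kernel weight construction, spreading/interpolation
scatter-gather, and the fused per-element stress assembly) are compiled
with numba; the pure-numpy reference implementations remain the public
API and the compiled kernels are cross-checked against them in the unit
tests to 1e-14. A desk16 step costs ≈15–20 ms on one core; the two-cycle
smoke run executes ≈25k steps in 6–8 minutes.

## Known limitations

* The immersed thin wall is leaky at coarse grids (marker spacing ≈ h);
  quantitative pressure-holding, stagnant-zone geometry and dilation
  require the full-resolution configuration.
* Desk-scale phase durations are distorted by the compressed cycle and
  the kernel-scale coaptation gap (see above).
* No leaflet contact model: coaptation is resisted hydrodynamically
  (squeeze film) and by the reverse-pressure phase.
* One-point quadrature linear tetrahedra represent thin-shell bending
  only bluntly; stress concentrations at the free edge are qualitative
  at desk resolutions.
* Checkpoint restart is bit-exact at the state level; metrics continue
  identically on the same platform.

## Verification configurations

The steady Poiseuille check drives a bulge-free rigid tethered tube
(32×32×96 grid) with 0.2 mmHg end-to-end pressure applied over the lumen
disc, using the 3-point kernel (the narrowest support gives the sharpest
wall and roughly halves the effective-radius bias of the 4-point
kernel); after a 0.45 s spin-up from rest the centreline velocity sits
within ~7% of ΔP·R²/(4μL) and the radial profile is quadratic to
R² > 0.999. The single-mode diffusion test matches the discrete heat
kernel to the O(dt) time-integration error and the continuum one to the
O(h²) spatial error.
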