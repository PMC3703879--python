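# Methods

`perifem` evaluates the load transfer from platform-switched threaded dental
implants into peri-implant bone with a linear, static, three-dimensional
finite-element model, and condenses the stress state into a
principal-stress-based overloading risk index over defined control volumes.
This note records the model, its assumptions, the numerical choices, and the
limits of what the synthetic set-up can show.

## The mechanical model

**Domain.** A synthetic maxillary premolar bone segment: a prismatic body of
40 mm mesiodistal span whose cross-section is a rounded trapezoid (crest
width 16 mm, base 14 mm, height 16 mm, lower corners rounded at 1.5 mm) with
a cortical shell of 2.0 mm mean thickness enclosing a trabecular core. The
section is deliberately wider than the alveolar ridge alone: it stands in
for the ridge plus the adjoining palatal bone mass, so that the lateral
cortical plates do not artificially brace the implant (with a 12 mm section
the anchorage becomes insensitive to implant length and marginal bone loss,
which contradicts the behaviour the comparative studies probe).

**Implants.** Eleven parametric designs (catalogue labels 1–10 and A):
diameters 3.5–4.3 mm, in-bone lengths 5.5–11 mm, two two-start thread forms
(saw-tooth `T0/30`: flanks at 120°/90° from the axis, free thickness
0.33 mm; trapezoid `T10/30`: 120°/100°, 0.25 mm), same (`ST`) or different
(`DT`, 0.38/0.19 mm) truncation per start, and an optional helical milling
groove (SM 0.3×0.15 mm, LM 0.6×0.3 mm — dimensions are package assumptions).
Threads are represented as **annular rings**: circumferential fins with the
exact 2D thread cross-section, protruding from the core at the start spacing
of 0.6 mm; `DT` truncates every second fin at half depth. The apex is a
rounded dome (quarter-ellipse of height 0.7 × core radius) — a sharp flat
tip is both unphysical for this implant family and a spurious stress raiser.
Platform switching: the abutment connection diameter is 0.75 D, leaving an
exposed platform ledge with a 45° × 0.3 mm lead-in bevel (implants 1–10).
The helical milling groove is carried by the solid model (membership and
volume) but not by the axisymmetric mesh; designs differing only in milling
are mechanically identical here, consistent with the secondary role milling
plays in the study's own findings.

**Placement and crestal morphology.** The platform sits 0 / 0.5 / 1.0 mm
below the outer crest (P0 / P05 / P1). Subcrestal placements carry a
horizontal bone-apposition collar of 0.25 mm mean thickness over the
platform ledge, rising at 45° back to the crest. The collar is bonded to
the *horizontal* platform but separated from the abutment wall by a 0.1 mm
free seam (the transmucosal biologic seam); bonding bone to the abutment
wall creates a spurious pinched load path. Crestal placement models
marginal bone loss as an axisymmetric conical crater (45° wall) of depth
`fraction × cortical thickness`; the cortical/trabecular boundary is
anatomically fixed (the pristine shell), so cratering thins the cortical
ring rather than displacing it.

**Materials and load.** Homogeneous isotropic linear elasticity per region:
titanium alloy implant/abutment E = 114 000 MPa, ν = 0.34; cortical bone
13 700 MPa, ν = 0.30; trabecular bone 500 MPa, ν = 0.30. Full
osseointegration is displacement continuity through shared mesh nodes — no
contact or friction. The functional load is 100 N buccolingual (+x) plus
250 N intrusive (−z), a resultant of ≈269 N at ≈68° to the occlusal plane,
applied 7 mm above the bone surface as a uniform traction over the abutment
top face (statically equivalent to the point load; by Saint-Venant the
choice is immaterial in bone). All displacement DOFs are fixed on the two
coronal cut faces. The model is mirror-symmetric about the loading plane
y = 0, and studies solve the half domain with u_y = 0 on the symmetry plane
(a full-domain mode exists).

## Stress measures and control volumes

At every bone Gauss point, with principal stresses σ₁ ≥ σ₂ ≥ σ₃:

    σ_C = min(σ₁, σ₂, σ₃, 0),   σ_T = max(σ₁, σ₂, σ₃, 0)
    R = |σ_C|/σ_C0 + σ_T/σ_T0

with admissible levels σ_C0 = 115 MPa / σ_T0 = 180 MPa for cortical bone
and 5 MPa in both signs for trabecular bone; R > 1 flags a locally critical
state. Statistics are taken over the control volume: bone within
δ = 0.25 D of the implant surface (exact point-to-profile distance in the
(ρ, z) half-plane), split into the cortical part Ω_c and three trabecular
subregions of equal axial length (crestal / intermediate / apical), the
span running from the most coronal trabecular member point to the implant
apex. Means are volume-weighted over member Gauss points (plain averaging
is available); peaks are raw Gauss-point extrema by default, with a
volume-weighted percentile option. R is evaluated pointwise before any
aggregation.

**On peaks.** The bonded bi-material corners of this model — the collar
free edge, thread-fin roots, and above all the implant/cortical/trabecular
triple junction — carry singular linear-elastic fields. Raw Gauss-point
maxima there grow under refinement (measured: the trabecular-crest peak
roughly doubles from hi/D = 0.2 to 0.05) and are therefore mesh-scale
quantities, not converged physical stresses. They are retained as the
default because they match the stated evaluation at Gauss points; the
percentile peak is the mesh-robust alternative. Comparative percentages
between scenarios meshed identically cancel part of this sensitivity but
remain noisy at desk scale — a caveat that applies to every peak-based
number this package prints.

## Discretisation

The mesher is a deterministic structured generator (no external meshing
library): a body-fitted polar grid around the implant axis whose innermost
bone column follows the exact thread profile, whose top follows the
morphology surface, and whose outer boundary follows the segment walls
(with rays through the section corners); cells are split by the Kuhn
six-tetrahedra pattern (conforming on structured grids) and promoted to
10-node tetrahedra with straight mid-edges. Region tags come from
classifying element centroids against the implicit solids; the
cortical/trabecular boundary and the morphology surfaces are node-aligned
to avoid staircase artefacts at the 27× stiffness jump.

Resolution is controlled by the two-zone size field h0/D and hi/D. The
peri-implant ratio is the accuracy driver; the crestal band (collar plus
cortical thread engagement) gets a denser axial station budget
(0.3 hi, floor 35 µm), the thread band below the crestal zone uses the
volume-equivalent smooth interface radius, and far-field columns blend to
an evenly graded axial ladder. Mesh-size presets, chosen for a 1-CPU/8 GiB
budget: hi/D = 0.2 for the test suite (≈25 k DOF, ≈12 s per solve) and
hi/D = 0.15 for the acceptance studies (≈40 k DOF); the classical
peri-implant ratio hi/D = 0.01 is cluster-scale and out of reach here.
Intentionally anisotropic thin layers near fins and collar mean the
scenario quality gate is an inversion/collapse guard (floor 1e-4 on the
6√2·V/l_max³ shape measure); isotropic benchmark meshes use 0.05.

Assembly uses the pure displacement formulation with 4-point Gauss
quadrature (exact for straight tet10 stiffness); the solve is a direct
sparse factorisation (deterministic); the traction resultant matches the
load vector to machine precision, and equilibrium/energy identities are
asserted in the tests.

## Error control

Zienkiewicz–Zhu recovery builds a nodal stress field per material region
(never averaging across material interfaces, where the true stress is
discontinuous): volume-weighted averaging of per-element nodal
extrapolations by default (exact for element-wise linear fields), with a
superconvergent-patch least-squares mode as an experimental option. The
global energy error norm is

    e_E = 100 · √( ‖σ* − σ_h‖²_E / (‖σ*‖²_E + ‖σ* − σ_h‖²_E) )  [%]

accepted at ≤ 5 %. On the Lamé thick-walled-cylinder benchmark the estimate
tracks the closed-form error within a factor 0.7–0.8 at all tested
refinements. The displacement error norm is interpreted as the relative L2
change between successive refinements (a single-mesh "displacement error"
is not well defined), accepted at ≤ 0.5 %. Because the scenario meshes'
geometric fidelity is tied to their resolution, the convergence walk
refines a fixed base mesh by global red (1:8) subdivision so that both
indicators measure pure discretisation error; the acceptance run uses a
29 mm reduced-span segment and two levels (memory bounds a third). At desk
scale the walk reaches ≈11 % energy norm and ≈7 % displacement change —
honestly flagged as not converged against the 5 % / 0.5 % thresholds, which
the original cluster-scale meshes met.

## Synthetic CT

The generator rasterises the bone solids into a Hounsfield-unit volume with
class means 0 / 400 / 1200 HU (package choices) plus Gaussian noise, and the
segmentation applies the calibrated thresholds: soft ≤ 150 HU < trabecular
≤ 750 HU < cortical. It emulates only the intensity-threshold step of a CT
pipeline: no scanner physics, partial-volume effects, registration, or
surface reconstruction. FE geometry always comes from the parametric
solids, never from the voxel volume.

## What the synthetic set-up can and cannot show

Everything downstream of geometry — the element formulation, solver, error
estimator, stress measures and region statistics — is verified against
closed forms and independent oracles. The comparative studies, however, run
on a synthetic segment with sharp-cornered axisymmetric threads rather than
a patient-derived maxilla with filleted helical threads, and at mesh ratios
10–20× coarser than the original cluster-scale analyses. Consequences
observed at desk scale, at the fixed study conditions (never re-tuned on
outcomes):

* the diameter effect (≈36 % cortical peak reduction for D 3.6→4.3) and the
  length effect (≈16 % for L 5.5→9), and their ordering, are reproduced;
* the thread-shape effect on the cortical compressive peak is *not*
  reproduced (≈0–3 % vs ≈24 %): with annular fins the collar/neck bearing
  controls that peak regardless of flank shape — the true helical flank
  mechanics appear essential;
* bone-loss and positioning effects carry the right sign but smaller
  magnitude (+18 % cortical / +69 % trabecular at 50 % loss vs +120 %/+105 %):
  in a closed 40 mm segment part of the lateral load bypasses the crestal
  ring through the core and walls;
* pointwise R < 1 cannot be certified: the raw maximum sits at singular
  bonded corners and exceeds 1 at any affordable density.

Known limitations beyond the above: linear kinematics and materials, dry
isotropic homogeneous bone per region, perfect osseointegration, no
time-dependent remodelling, no gingival tissue, and the stand-in geometry
for the commercial reference implant (label A: D3.5/L11, trapezoid thread,
no milling, no bevel).
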