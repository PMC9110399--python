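# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of `aclrsim`. Units are fixed globally: mm, N, MPa,
degrees for reported angles (MPa·mm² = N keeps `k = E·A` unit-clean).

## Ligament spring model

Ligaments and grafts are bundles of tension-only springs with the
piecewise quadratic/linear force–strain law (toe region up to `2 ε_l`,
linear beyond), the standard nonlinear-spring representation for knee
ligaments. Parameters per bundle:

| parameter | meaning | default |
|---|---|---|
| `k` (N) | total bundle stiffness, `E·A` | per ligament (see below) |
| `ε_l` | linear strain limit | 0.03 |
| `ε_r` | reference (pre)strain at the assembly pose | per ligament |
| `L_r` (mm) | reference length = chord at assembly | measured at assembly |
| springs per bundle | discretization of the attachment footprint | 4 (toy), configurable; 10 is a typical choice for subject models |

`L₀ = L_r/(1+ε_r)` is resolved per spring when a model is assembled; the
assembly pose is full extension unless configured otherwise. Stiffness is
split evenly over a bundle's springs. Reported stiffnesses are rounded
half-away-from-zero to integer newtons at the reporting layer only.

The law is C0/C1 continuous at the branch junction and has the
closed-form inverse `ε = F/k + ε_l` (linear branch) /
`ε = √(4 F ε_l / k)` (toe), used for pretensioning.

Default per-ligament constants (stiffness from the morphometry estimates,
prestrain from the nonlinear-spring knee-model literature): ACL 12 759 N /
+0.06, PCL 12 804 N / −0.03, MCL 7 496 N / +0.04, LCL 2 556 N / +0.03.
A meniscal-root linear stiffness of 2000 N/mm is kept as a named export
constant; meniscal roots are not part of the reduced-order simulation.

## Cross-section morphometry

The ligament mesh's principal axis is the leading eigenvector of the raw
vertex covariance (an area-weighted variant is available; raw vertices are
the default as the simplest reading of mesh PCA). Planes normal to the
axis are spaced 1 mm ("one unit" in mm meshes; configurable) over the
length of the bounding-box main diagonal centered on the centroid, so
some stations necessarily miss the mesh; empty or open-contour stations
(end caps, segmentation holes) are dropped rather than repaired, and a
1e-6 mm² floor filters slivers. Station areas are shapely polygon areas
of the closed section contours, combined even-odd so disjoint components
sum and voids subtract. A near-tie of the two leading eigenvalues (within
1 %) raises a degenerate-shape warning.

The mean sliced area of a faceted cylinder is biased low by the inscribed
polygon (−0.16 % at 64 facets); tolerance in tests scales accordingly.

## Tunnel paths and drilling

A tunnel is defined by four landmarks (tibial entry/footprint, femoral
footprint/exit). The path is straight within each bone; the
intra-articular blend is a cubic Bezier — a NURBS with uniform weights,
the degree/weight choice being this package's own — whose interior
control points lie along the straight directions at one third of the
footprint-to-footprint distance, guaranteeing C1 joins. Double-bundle
plans are validated by requiring positive clearance between the two swept
tunnel cylinders (densely sampled path-to-path distances).

Only the straight segments are drilled (the blend spans the joint space).
The boolean difference is evaluated on a signed-distance grid: exact
point–triangle distance with a parity-ray inside test for the bone,
analytic capped-cylinder distance for the drill (extended 10 % beyond the
segment so its caps clear the bone faces), combined by `min`, and
re-surfaced with marching cubes. Choices that matter:

* grid pitch defaults to `radius/8`; the grid is anchored to the bone's
  bounding box and offset by an irrational fraction of the pitch so mesh
  faces of axis-aligned fixtures never coincide with grid points (which
  would make the inside/outside sign ambiguous);
* degenerate marching-cubes triangles are disallowed, making the output
  watertight;
* removed volume converges to `π r² · thickness` as the pitch shrinks
  (0.9 % error at the default pitch on the 20 mm block fixture);
* translations of bone + landmarks reproduce the drilled mesh exactly
  (the grid translates with the bone); under rotations the result is only
  volume-equivalent, a known grid anisotropy of level-set booleans;
* a wall check casts lateral rays from interior axis stations and raises
  a drilling error if the bone cover is thinner than the drill radius.

This level-set formulation is the package's CSG backend; its accuracy is
grid-bound, which is acceptable because drilled geometry feeds rigid-bone
export and volume bookkeeping, not contact mechanics.

## Graft meshing

The circular section is meshed as an O-grid: a central square block
(half-width `r_b/2`, 5 divisions per side by default) plus four
transition blocks (3 radial layers) blending to the circle — no
degenerate center wedges, minimum scaled Jacobian ≈ 0.71 for a straight
cylinder. Twenty boundary chords leave a 1.6 % inscribed-polygon volume
deficit at the default resolution; the deficit shrinks quadratically with
resolution. Axial layers follow a `(span, n_layers)` schedule; the
default grades a 2× finer spacing into the end 10 % of the length, so the
tunnel-insertion element sets are denser than mid-span.

`n` bundles of radius `r_b = R·sin(π/n)/(1+sin(π/n))` sit on a regular
n-gon of circumradius `R − r_b` (tangent-or-separated, contained).
Twisting rotates each cross-section rigidly about the graft axis by
`θ(z) = rate·z`, so bundle centers trace helices and disjoint bundles
stay disjoint; the default total twist is 90° over the intra-articular
blend length (no published value exists; configurable). The sweep
transports each section to the path point at matching arc length using
double-reflection rotation-minimizing frames, which add no spurious
torsion on top of the explicit twist; it refuses paths whose blend
curvature radius is below the section radius. Hexes can be split 6-to-1
into tetrahedra; the split preserves volume to within the face-warp error
(< 1 % for these gently curved elements).

## Joint coordinate system

Grood–Suntay angles are extracted as an intrinsic x–y′–z″ Euler
decomposition of the femur-relative-to-tibia rotation (x = femoral ML,
z = tibial SI, the middle axis being the floating axis), translations as
components of the inter-origin vector along `(e1, e2, e3)`; the inverse
solves the small non-orthogonal system exactly, so pose → transform →
pose round-trips to < 1e-9 away from the |adduction| = 90° singularity,
which raises an explicit error. Anatomical frames are caller-supplied
inputs (landmark-built helpers live in the fixtures).

## Reduced-order laxity simulation

The continuum FE solve is replaced by a rigid femur in quasi-static
equilibrium on the spring bundles plus compression-only contacts; the
tibia is fixed. This reproduces the scalar outputs of interest — AP
displacement, graft tension, a stress proxy — but not stress fields.

* **Contacts.** The tibiofemoral articulation is a plane contact: two
  femoral condyle points against the tibial plateau plane with a linear
  penalty (5000 N/mm). A point-vs-plane formulation was chosen over
  point-pair springs because compressed struts destabilize the transverse
  directions, whereas a plane penalty is transversally neutral.
* **Solver.** Free Grood–Suntay DoFs are solved by damped Newton on the
  generalized residual (exact spring tensions, O(h²) finite-difference
  geometry derivatives, batched; FD Jacobian), with prescribed values and
  the load ramped over substeps (default 8–10, fewer with warm starts).
  Globalization is an Armijo line search on the total potential with a
  steepest-descent fallback; near the root, full Newton steps are taken
  because potential differences fall below float resolution there.
  Convergence requires residuals < 1e-6 N and < 1e-6 N·mm.
* **Pretension.** The knee is held reduced (AP/ML prescribed zero,
  contact-supported DoFs equilibrated) at the fixation flexion angle;
  each graft spring's slack length is then set by the closed-form inverse
  so the bundle tension equals the pretension exactly at that pose, and
  frozen. The paper-style pressure load on the graft stump is statically
  equivalent to prescribed bundle tension for a uniform section.
* **Protocols.** Lachman: flexion prescribed (default 30°), int/ext
  rotation locked at 0, four DoFs free, 134 N posterior femoral force at
  the femoral frame origin; the reported displacement is relative to the
  zero-force equilibrium at the same flexion (signed, posterior
  negative). Drawer tests are the signed-force generalization.
* **Stress proxy.** Graft axial force divided by the packed section area
  `n·π·r_b²` — a proxy for, never an estimate of, the continuum maximum
  principal stress.
* **Graft surrogate.** The 3D graft mesh is represented mechanically by
  an effective axial bundle with `k = E_eff · n π r_b²`. Default
  harvest-site moduli (semitendinosus 362, patellar tendon 307, gracilis
  612 MPa) are package defaults from tendon tensile-testing literature
  and should be overridden for subject-specific work.

### Sensitivity grid

Cruciate stiffness (±30 %) and prestrain (±15 %) multipliers on a 5 %
step form the 13 × 7 = 91-model factorial; one multiplier pair applies
jointly to ACL and PCL (per-ligament mode is available), collaterals stay
fixed, matching the convention that collateral action is secondary for AP
laxity. Each combination is simulated over the experimental (flexion,
force) conditions and scored by mean squared displacement error; ranking
ties prefer multipliers closest to 1. Grid evaluation warm-starts each
condition from the previous combination's equilibrium.

## Synthetic fixtures: what they emulate, and what they do not

The toy knee is a geometric caricature built for testability, not
anatomy: block bones (with an intercondylar notch block and tibial shaft
block so attachments lie within 2 mm of a mesh surface), mirror-symmetric
attachments about the sagittal plane, a flat plateau contact. Its
cruciates attach near the flexion axis on the femur (near-isometric) and
run obliquely (~35 mm, AP direction cosine ≈ 0.45) to deep tibial
insertions, so the knee operates in the spring toe region and shows a
clinically plausible laxity of a few mm under the 134 N drawer force —
a deliberate design requirement, because parameter identifiability from
noisy laxity curves (0.1 mm measurement noise) needs displacement
sensitivity per 5 % grid step on the order of the noise. The graft
attachment geometry makes the graft chord grow monotonically with flexion
up to ≈ 60°, which is what produces the clinically reported
laxity-increase above 30° fixation; only that above-30° trend direction
is asserted in tests.

Synthetic laxity curves are simulator outputs at chosen multipliers over
a default schedule of anterior/posterior drawers (±134 N at 0/10/20/30°
of flexion) plus seeded Gaussian noise (default sd 0.1 mm — the
measurement noise of the emulated experiments is not characterized
anywhere, so this is an assumption).

What passing tests on these fixtures demonstrate: correctness of the
mechanics, geometry and calibration machinery, and the qualitative
directions of the what-if studies. What they do not demonstrate: accuracy
on real knees, where articular geometry, menisci, cartilage compliance
and muscle loads shape the response.

## Degenerate inputs and tie-breaks

Coincident landmarks, non-positive radii/stiffnesses/strain limits,
zero-length spring chords, schedules that do not sum to the length,
interpenetrating bundle packings, over-tight sweep curvature, gimbal
poses, empty slice profiles and unknown material tags all raise typed
errors (`aclrsim.errors`). The principal-axis sign is fixed by making the
largest-magnitude component positive; sensitivity ranking ties break
toward multipliers nearest unity, then prestrain.

## Problem sizes

Default test and acceptance runs use the sizes above: 64-facet tubes,
20 mm block bones at 0.25 mm grid pitch, 4-spring bundles, 8-condition
laxity schedules, 91-model grids, and 50-replicate recovery studies.
These sizes keep every quantity's discretization error well inside its
assertion tolerance while remaining quick to regenerate from code.
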