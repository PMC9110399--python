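# aclrsim

Automated modeling of anterior cruciate ligament reconstruction (ACLR)
surgery for musculoskeletal biomechanics: subject-specific ligament
stiffness estimation from segmented meshes, virtual tunnel and graft
planning, hexahedral graft meshing, knee model assembly with nonlinear
spring ligaments, FE-input export, and a reduced-order Lachman-test
simulator for sensitivity and "what-if" studies.

It is written for biomechanics researchers and surgical-simulation
engineers who want to go from segmented knee geometry (STL/PLY/OBJ, mm)
and a handful of surgery parameters — technique (single- vs double-
bundle), graft radius, pretension, fixation angle, harvest site — to a
simulated post-operative knee laxity, without driving a GUI.

## The models at its core

**Ligaments** are bundles of tension-only nonlinear springs with the
piecewise force–strain law

```
F(ε) = 0                     ε < 0
     = ¼ k ε² / ε_l          0 ≤ ε ≤ 2 ε_l        (toe region)
     = k (ε − ε_l)           ε > 2 ε_l            (linear region)
```

with stiffness `k = E·A` (MPa·mm² = N), linear strain limit `ε_l = 0.03`,
and slack length `L₀ = L_r / (1 + ε_r)` derived from the reference length
at the assembly pose and a reference prestrain `ε_r`. `k` is split evenly
over the springs of a bundle. The cross-sectional area `A` is estimated
from a segmented ligament mesh by slicing it with planes normal to its
principal (PCA) axis, 1 mm apart across the bounding-box diagonal, and
averaging the closed-contour areas.

**Surgery**: four landmarks per tunnel define a composite path — two
straight bone segments joined by a cubic intra-articular blend (a NURBS
with uniform weights, C1 joins). Tunnels are carved by subtracting a
capped drilling cylinder from the bone via a signed-distance level-set
boolean. The graft is an O-grid (butterfly) hexahedral cylinder; multiple
bundles are packed symmetrically (`r_b = R·sin(π/n)/(1+sin(π/n))`),
twisted into a rope, and swept along the path with rotation-minimizing
frames.

**Kinematics** use the Grood–Suntay joint coordinate system: flexion
about the femoral medial-lateral axis, internal–external rotation about
the tibial superior-inferior axis, ad/abduction about the floating axis,
translations resolved along the same triad.

**Laxity simulation** replaces the continuum FE solve with a rigid femur
in quasi-static equilibrium on the spring bundles plus compression-only
tibiofemoral contacts. The Lachman protocol applies graft pretension at a
fixation flexion angle (closed-form inverse of the spring law), then
flexes the knee to 30° and applies a 134 N posterior femoral force with
internal–external rotation locked. A 13 × 7 factorial sensitivity grid
(stiffness ±30 %, prestrain ±15 %, 5 % steps → 91 models) ranks cruciate
parameters against anterior/posterior laxity curves by mean squared
displacement error.

## Worked example

Estimate ligament stiffness from a mesh (here a synthetic 3 mm tube whose
true section area is π·3² ≈ 28.27 mm²):

```bash
$ aclrsim area tube_r3_l30.stl -e 355
{
  "axis": [0.0, 0.0, 1.0],
  "n_stations": 30,
  "mean_area_mm2": 28.2289,
  "stiffness_N": 10021.3
}
```

The mean sliced area (28.23 mm², 0.2 % below the analytic value at 64
circumferential facets) times the Young's modulus of 355 MPa gives the
bundle stiffness in newtons.

Simulate the Lachman test on the built-in toy knee, healthy versus
single-bundle reconstructed (4 mm semitendinosus graft, 80 N pretension,
fixed at 20° of flexion):

```bash
$ aclrsim lachman --technique RM
{
  "variant": "RM",
  "relative_ap_displacement_mm": -2.5402,
  ...
}
$ aclrsim lachman --technique SB --radius 4 --pretension 80 --fixation-angle 20
{
  "variant": "SB",
  "relative_ap_displacement_mm": -0.7168,
  "graft_axial_force_N": 115.21,
  "graft_stress_proxy_MPa": 2.292,
  ...
}
```

The healthy reference knee displaces 2.54 mm posteriorly under the 134 N
Lachman force; this reconstruction overconstrains the toy knee (0.72 mm),
and the graft carries 115 N, i.e. a 2.3 MPa axial stress proxy. Sweeps
over radius, pretension, fixation angle and SB/DB technique
(`aclrsim sweep --radii 2.5,3.5,4.5`) tabulate the absolute displacement
difference to the reference model for each option.

Other commands: `aclrsim fixtures` (write all synthetic meshes/curves),
`plan`, `drill`, `graft`, `export-demo` (FEBio 3.0 `.feb`),
`sensitivity` (rank the 91-model grid against a laxity curve file).

## Limitations

The laxity simulator is a reduced-order surrogate: it reproduces scalar
outputs (displacements, graft tension, an axial stress proxy) but not
continuum stress fields, contact pressure maps, or viscoelastic effects.
Cartilage and menisci appear only as named contact-pair placeholders in
the FE export. See `docs/methods.md` for the full model description,
parameter defaults, and numerical choices.
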