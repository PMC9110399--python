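"""Synthetic geometry and data generators.

Every fixture carries its analytic ground truth (section areas, volumes,
small-displacement laxity coefficients) as metadata, so module tests can
compare against closed-form values instead of recomputing them from the
artifact under test.  Seeded generation is bit-reproducible.

Fixtures provided:

* analytic tubes (straight / bent, circular / elliptic sections) for the
  cross-section morphometry oracle;
* block "bones" with tunnel landmarks for the drilling oracle;
* a toy knee -- rigid femur block on a tibial plateau, cruciate and
  collateral spring bundles, compression-only condyle contacts -- whose
  anterior-posterior response decouples in the small-strain limit;
* an antagonist-pair 1-DoF knee with an exact closed-form force-
  displacement solution;
* synthetic noisy laxity curves emulating anterior/posterior drawer
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import InvalidParameterError
from .graft_meshing import GraftSpec
from .knee_assembly import (
    BodyFrame,
    Graft,
    KneeModel,
    PlaneContact,
    assemble_model,
)
from .laxity_sim import (
    apply_multipliers,
    graft_effective_bundle,
    run_drawer,
)
from .ligament_mechanics import LigamentBundle, SpringLaw
from .surgery_planning import LandmarkSet

__all__ = [
    "FixtureSpec",
    "make_tube",
    "make_block_bone",
    "make_toy_knee",
    "make_toy_aclr",
    "make_antagonist_pair_knee",
    "make_synthetic_laxity_curve",
    "DEFAULT_LAXITY_SCHEDULE",
    "TOY_LIGAMENT_LAWS",
]

#: Default drawer-test conditions for synthetic laxity curves:
#: (flexion deg, signed anterior force N) pairs -- anterior and posterior
#: drawer at four flexion angles, at the Lachman force magnitude.
DEFAULT_LAXITY_SCHEDULE = tuple(
    (f, s * 134.0) for f in (0.0, 10.0, 20.0, 30.0) for s in (1.0, -1.0)
)

#: Toy-knee bundle parameters: stiffness (N) from the subject-specific
#: morphometry estimates, reference prestrains from the nonlinear-spring
#: ligament literature.
TOY_LIGAMENT_LAWS = {
    "ACL": {"k": 12759.0, "eps_r": 0.06},
    "PCL": {"k": 12804.0, "eps_r": -0.03},
    "MCL": {"k": 7496.0, "eps_r": 0.04},
    "LCL": {"k": 2556.0, "eps_r": 0.03},
}

# toy-knee attachment geometry (mm): femoral points are femur-frame-local,
# tibial points world; the tibial plateau plane is z = 0.  The cruciates
# attach near the flexion axis on the femoral side (near-isometric) and run
# obliquely to deep tibial insertions (~35 mm long, AP direction cosine
# ~0.45), so the knee operates in the spring toe region with a clinically
# realistic laxity of a few mm under the 134 N drawer force.
_TOY_ATTACHMENTS = {
    "ACL": ((0.0, -6.0, 3.0), (0.0, 10.0, -30.0)),
    "PCL": ((0.0, 6.0, 3.0), (0.0, -10.0, -30.0)),
    "MCL": ((-25.0, 0.0, 10.0), (-25.0, 0.0, -5.0)),
    "LCL": ((25.0, 0.0, 10.0), (25.0, 0.0, -5.0)),
}
_TOY_GRAFT_FEMORAL = np.array([0.0, 0.0, 1.5])
_TOY_GRAFT_TIBIAL = np.array([0.0, 25.0, -5.0])


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the command-line generator)."""

    kind: str  # tube | block_bone | toy_knee | laxity_curve
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def make_tube(
    radius: float,
    length: float,
    bend_curvature: float = 0.0,
    section: str = "circle",
    semi_axes=(4.0, 2.0),
    facets: int = 64,
    axial_steps: int = 60,
) -> trimesh.Trimesh:
    """Watertight tube mesh with its analytic section area attached.

    The centerline runs along +z (or along a circular arc of curvature
    ``bend_curvature`` in the x-z plane); the cross-section is a circle of
    ``radius`` or an ellipse with ``semi_axes``.  The analytic area
    (pi r^2 or pi a b) is stored in ``mesh.metadata["analytic_area"]``.
    """
    if length <= 0:
        raise InvalidParameterError("tube length must be > 0")
    if section == "circle":
        a = b = float(radius)
        if radius <= 0:
            raise InvalidParameterError("tube radius must be > 0")
    elif section == "ellipse":
        a, b = (float(x) for x in semi_axes)
        if a <= 0 or b <= 0:
            raise InvalidParameterError("ellipse semi-axes must be > 0")
    else:
        raise InvalidParameterError("section must be 'circle' or 'ellipse'")

    theta = np.linspace(0.0, 2 * np.pi, facets, endpoint=False)
    ring = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    s = np.linspace(0.0, length, axial_steps + 1)
    verts = []
    for si in s:
        if bend_curvature == 0.0:
            center = np.array([0.0, 0.0, si])
            ex = np.array([1.0, 0.0, 0.0])
            ey = np.array([0.0, 1.0, 0.0])
        else:
            R = 1.0 / bend_curvature
            ang = si / R
            center = np.array([R * (1 - np.cos(ang)), 0.0, R * np.sin(ang)])
            # radial direction in the bend plane, perpendicular to the tangent
            ex = np.array([-np.cos(ang), 0.0, np.sin(ang)])
            ey = np.array([0.0, 1.0, 0.0])
        verts.extend(center + ring[:, 0:1] * ex + ring[:, 1:2] * ey)
    verts = np.array(verts)
    faces = []
    for i in range(axial_steps):
        base0, base1 = i * facets, (i + 1) * facets
        for j in range(facets):
            j2 = (j + 1) % facets
            faces.append([base0 + j, base0 + j2, base1 + j2])
            faces.append([base0 + j, base1 + j2, base1 + j])
    # end caps: triangle fans around the ring centroids
    c0 = len(verts)
    verts = np.vstack([verts, verts[:facets].mean(axis=0), verts[-facets:].mean(axis=0)])
    for j in range(facets):
        j2 = (j + 1) % facets
        faces.append([c0, j2, j])  # bottom cap
        faces.append([c0 + 1, axial_steps * facets + j, axial_steps * facets + j2])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    mesh.fix_normals()
    mesh.metadata["analytic_area"] = np.pi * a * b
    mesh.metadata["length"] = float(length)
    return mesh


def make_block_bone(dims=(20.0, 20.0, 20.0), center=(0.0, 0.0, 0.0), axis="z"):
    """Axis-aligned block bone with through-tunnel landmarks.

    Returns ``(mesh, landmarks)``: the tibial straight segment of the
    landmark set spans the block along ``axis`` so drilling it removes an
    analytic cylinder volume ``pi r^2 * dims[axis]`` (stored in
    ``mesh.metadata["thickness"]``).
    """
    dims = np.asarray(dims, dtype=float)
    center = np.asarray(center, dtype=float)
    if np.any(dims <= 0):
        raise InvalidParameterError("block dimensions must be > 0")
    mesh = trimesh.creation.box(extents=dims)
    mesh.apply_translation(center)
    i = "xyz".index(axis)
    e = np.zeros(3)
    e[i] = 1.0
    half = dims[i] / 2.0
    landmarks = LandmarkSet(
        tibia_entry=center - half * e,
        tibia_footprint=center + half * e,
        femur_footprint=center + (half + dims[i]) * e,
        femur_exit=center + (half + 2 * dims[i]) * e,
    )
    mesh.metadata["thickness"] = float(dims[i])
    mesh.metadata["volume"] = float(np.prod(dims))
    return mesh, landmarks


def _spread(point, n, axis=0, width=3.0):
    """n copies of a point fanned symmetrically along one coordinate axis."""
    point = np.asarray(point, dtype=float)
    offsets = np.linspace(-width / 2, width / 2, n) if n > 1 else np.array([0.0])
    pts = np.tile(point, (n, 1))
    pts[:, axis] += offsets
    return pts


def _toy_bundles(n_springs: int, laws: dict):
    bundles = []
    for name, (fem, tib) in _TOY_ATTACHMENTS.items():
        p = dict(TOY_LIGAMENT_LAWS[name], **laws.get(name, {}))
        axis = 1 if name in ("MCL", "LCL") else 0  # keep mirror symmetry in x
        bundles.append(
            LigamentBundle(
                name=name,
                origins=_spread(fem, n_springs, axis=axis),
                insertions=_spread(tib, n_springs, axis=axis),
                law=SpringLaw(k=p["k"], eps_r=p["eps_r"]),
            )
        )
    return bundles


def _toy_bones():
    """Block bones with an intercondylar notch block (femur) and a shaft
    block (tibia) so cruciate attachments sit near mesh surfaces.  The
    combined meshes are attachment/export geometry, not contact surfaces.
    """
    shaft_f = trimesh.creation.box(extents=(50, 50, 40))
    shaft_f.apply_translation((0, 0, 20))
    notch = trimesh.creation.box(extents=(16, 14, 8))
    notch.apply_translation((0, 0, 4))
    femur = trimesh.util.concatenate([shaft_f, notch])
    plateau = trimesh.creation.box(extents=(50, 50, 10))
    plateau.apply_translation((0, 0, -5))
    shaft_t = trimesh.creation.box(extents=(24, 22, 30))
    shaft_t.apply_translation((0, 0, -25))
    tibia = trimesh.util.concatenate([plateau, shaft_t])
    return femur, tibia


def _toy_contacts(contact_stiffness: float):
    return [
        PlaneContact(
            points=[(-15.0, 0.0, 0.0), (15.0, 0.0, 0.0)],
            plane_point=(0.0, 0.0, 0.0),
            normal=(0.0, 0.0, 1.0),
            stiffness=contact_stiffness,
        )
    ]


def make_toy_knee(
    n_springs: int = 4,
    contact_stiffness: float = 5000.0,
    laws: dict | None = None,
) -> KneeModel:
    """Healthy-reference (RM) toy knee.

    A femur block articulates on the tibial plateau plane z = 0 through
    two compression-only condyle contacts at x = +/-15 mm; ACL/PCL/MCL/LCL
    spring bundles attach mirror-symmetrically about the x = 0 plane, so
    anterior-posterior loading produces no medial-lateral or axial-rotation
    coupling.  ``laws`` can override per-bundle ``k`` / ``eps_r``.
    """
    femur, tibia = _toy_bones()
    model = assemble_model(
        "RM",
        BodyFrame.identity(),
        BodyFrame.identity(),
        _toy_bundles(n_springs, laws or {}),
        contacts=_toy_contacts(contact_stiffness),
        femur_mesh=femur,
        tibia_mesh=tibia,
    )
    model.metadata["plateau_plane_z"] = 0.0
    return model


def make_toy_aclr(
    technique: str = "SB",
    radius: float = 4.0,
    material: str = "semitendinosus",
    n_springs: int = 4,
    contact_stiffness: float = 5000.0,
    laws: dict | None = None,
    moduli: dict | None = None,
) -> KneeModel:
    """ACL-reconstructed toy knee (SB or DB) with unresolved graft bundles.

    The native ACL is removed; the graft's effective spring bundle runs
    from the femoral notch attachment to the anterior tibial tunnel exit.
    Pretension must be applied before laxity simulation.
    """
    femur, tibia = _toy_bones()
    bundles = [b for b in _toy_bundles(n_springs, laws or {}) if b.name != "ACL"]
    grafts = []
    if technique == "SB":
        offsets = [0.0]
        radii = [radius]
        names = ["graft-AM"]
    elif technique == "DB":
        offsets = [-2.0, 2.0]
        radii = [radius, radius]
        names = ["graft-AM", "graft-PL"]
    else:
        raise InvalidParameterError("technique must be 'SB' or 'DB'")
    for off, r, name in zip(offsets, radii, names):
        spec = GraftSpec(radius=r, n_bundles=1, material=material)
        bundle = graft_effective_bundle(
            spec,
            origins=_spread(_TOY_GRAFT_FEMORAL + [off, 0, 0], n_springs, axis=0, width=2.0),
            insertions=_spread(_TOY_GRAFT_TIBIAL + [off, 0, 0], n_springs, axis=0, width=2.0),
            moduli=moduli,
            name=name,
        )
        grafts.append(Graft(spec=spec, bundle=bundle))
    model = assemble_model(
        technique,
        BodyFrame.identity(),
        BodyFrame.identity(),
        bundles,
        grafts=grafts,
        contacts=_toy_contacts(contact_stiffness),
        femur_mesh=femur,
        tibia_mesh=tibia,
    )
    return model


def make_antagonist_pair_knee(k: float = 10000.0, eps_r: float = 0.09, half_span: float = 10.0):
    """1-DoF oracle: two equal antagonist springs along the AP axis.

    Both springs are prestrained into the linear branch, so for a posterior
    force ``F`` (with all DoFs but AP locked) the equilibrium displacement
    is exactly ``d = -F * L_0 / (2 k)``.  Returns ``(model, info)`` with the
    analytic compliance in ``info["compliance"]`` (mm/N).
    """
    if eps_r <= 2 * 0.03:
        raise InvalidParameterError("oracle springs must start in the linear branch")
    bundles = [
        LigamentBundle("ACL", [(0.0, -half_span, 0.0)], [(0.0, half_span, 0.0)],
                       SpringLaw(k=k, eps_r=eps_r)),
        LigamentBundle("PCL", [(0.0, half_span, 0.0)], [(0.0, -half_span, 0.0)],
                       SpringLaw(k=k, eps_r=eps_r)),
    ]
    model = assemble_model(
        "RM", BodyFrame.identity(), BodyFrame.identity(), bundles
    )
    L0 = 2 * half_span / (1 + eps_r)
    info = {
        "L_0": L0,
        "compliance": L0 / (2 * k),
        "max_linear_force": 2 * k * (eps_r - 2 * 0.03) * 0.9,
    }
    return model, info


def make_synthetic_laxity_curve(
    model: KneeModel,
    schedule=DEFAULT_LAXITY_SCHEDULE,
    noise_sd: float = 0.1,
    seed: int = 0,
    multipliers=(1.0, 1.0),
    ramp_substeps: int = 3,
) -> np.ndarray:
    """Noisy drawer-test curves from a (possibly rescaled) toy knee.

    Returns rows of ``(flexion deg, anterior force N, displacement mm)``;
    displacements are simulator outputs at the given cruciate stiffness /
    prestrain multipliers plus seeded Gaussian measurement noise
    (``noise_sd`` mm, default 0.1).
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise sd must be >= 0")
    m = apply_multipliers(model, multipliers[0], multipliers[1])
    rng = np.random.default_rng(seed)
    rows = []
    for flexion, force in schedule:
        res = run_drawer(m, flexion, force, ramp_substeps=ramp_substeps)
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        rows.append([flexion, force, res.relative_ap_displacement + noise])
    return np.array(rows)


def generate(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    kind = spec.kind
    if kind == "tube":
        return make_tube(**spec.parameters)
    if kind == "block_bone":
        return make_block_bone(**spec.parameters)
    if kind == "toy_knee":
        return make_toy_knee(**spec.parameters)
    if kind == "laxity_curve":
        params = dict(spec.parameters)
        model = make_toy_knee(**params.pop("knee", {}))
        return make_synthetic_laxity_curve(model, seed=spec.seed, **params)
    raise InvalidParameterError(f"unknown fixture kind {kind!r}")
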