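"""Knee model assembly: body frames, the Grood-Suntay joint coordinate
system, model variants (RM / SB / DB) and FE-input export.

The joint coordinate system follows Grood & Suntay: flexion about the
femoral medial-lateral axis ``e1``, internal-external rotation about the
tibial superior-inferior axis ``e3``, and ad/abduction about the floating
axis ``e2 = e3 x e1``; this is equivalent to an intrinsic x-y'-z'' Euler
decomposition of the femur-relative-to-tibia rotation.  Translations are
the components of the inter-origin vector along ``(e1, e2, e3)``.  All
rotations are right-hand-rule positive about their axis; angles are
reported in degrees, translations in mm.

Bones are rigid triangulated surfaces; ligaments are discrete nonlinear
spring bundles; the tibiofemoral articulation of the reduced-order model
is carried by compression-only plane contacts (a rigid-contact surrogate).
Models export to FEBio 3.0 ``.feb`` XML (springs as tabulated
force-displacement curves) and to legacy VTK files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from scipy.spatial.transform import Rotation

from . import _sdf, _vtk
from .errors import AssemblyError, ExportError, InvalidParameterError, SingularPoseError
from .graft_meshing import GraftSpec, HexMesh
from .ligament_mechanics import (
    MENISCAL_ROOT_STIFFNESS,
    LigamentBundle,
    blankevoort_force,
)

__all__ = [
    "BodyFrame",
    "JointPose",
    "PlaneContact",
    "Graft",
    "KneeModel",
    "grood_suntay_pose",
    "pose_to_transform",
    "assemble_model",
    "export_feb",
    "read_feb",
    "export_vtk",
]


@dataclass(frozen=True)
class BodyFrame:
    """Anatomical body frame: origin (mm) and right-handed orthonormal axes.

    ``axes`` columns are the medial-lateral, anterior-posterior and
    superior-inferior directions in world coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        R = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "axes", R)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidParameterError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidParameterError("frame axes must be right-handed")

    @property
    def ml(self):
        return self.axes[:, 0]

    @property
    def ap(self):
        return self.axes[:, 1]

    @property
    def si(self):
        return self.axes[:, 2]

    @classmethod
    def identity(cls) -> "BodyFrame":
        return cls(np.zeros(3), np.eye(3))


@dataclass
class JointPose:
    """Grood-Suntay 6-DoF pose of the femur relative to the tibia.

    Angles in degrees (right-hand rule about e1, e2, e3), translations in
    mm along (e1, e2, e3) = (femoral ML, floating, tibial SI).
    """

    flexion: float = 0.0
    adduction: float = 0.0
    external_rotation: float = 0.0
    medial_lateral: float = 0.0
    anterior_posterior: float = 0.0
    superior_inferior: float = 0.0

    def __post_init__(self):
        for name in ("flexion", "adduction", "external_rotation"):
            v = float(getattr(self, name))
            if not (-180.0 < v <= 180.0):
                raise InvalidParameterError(f"{name} must lie in (-180, 180], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion, self.adduction, self.external_rotation,
             self.medial_lateral, self.anterior_posterior, self.superior_inferior]
        )

    @classmethod
    def from_array(cls, q) -> "JointPose":
        q = np.asarray(q, dtype=float).reshape(6)
        return cls(*q)


def grood_suntay_pose(femur: BodyFrame, tibia: BodyFrame) -> JointPose:
    """Extract the 6-DoF joint pose from the two body frames.

    Raises :class:`SingularPoseError` when the femoral ML axis is parallel
    to the tibial SI axis (the floating axis is undefined).
    """
    e1 = femur.ml
    e3 = tibia.si
    if abs(float(e1 @ e3)) > 1.0 - 1e-9:
        raise SingularPoseError("femoral ML axis is parallel to tibial SI axis")
    R_rel = tibia.axes.T @ femur.axes
    th1, th2, th3 = Rotation.from_matrix(R_rel).as_euler("XYZ", degrees=True)
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)
    H = femur.origin - tibia.origin
    return JointPose(th1, th2, th3, float(H @ e1), float(H @ e2), float(H @ e3))


def pose_to_transform(pose: JointPose, tibia: BodyFrame | None = None) -> np.ndarray:
    """4x4 world placement of the femur frame realizing ``pose``.

    The transform maps femur-frame-local points to world coordinates.
    Exact inverse of :func:`grood_suntay_pose`.
    """
    if tibia is None:
        tibia = BodyFrame.identity()
    R_rel = Rotation.from_euler(
        "XYZ", [pose.flexion, pose.adduction, pose.external_rotation], degrees=True
    ).as_matrix()
    Rf = tibia.axes @ R_rel
    e1 = Rf[:, 0]
    e3 = tibia.axes[:, 2]
    if abs(float(e1 @ e3)) > 1.0 - 1e-9:
        raise SingularPoseError("pose is gimbal-singular (|adduction| = 90 deg)")
    e2 = np.cross(e3, e1)
    e2 = e2 / np.linalg.norm(e2)
    E = np.column_stack([e1, e2, e3])
    d = np.array([pose.medial_lateral, pose.anterior_posterior, pose.superior_inferior])
    H = np.linalg.solve(E.T, d)
    T = np.eye(4)
    T[:3, :3] = Rf
    T[:3, 3] = tibia.origin + H
    return T


@dataclass
class PlaneContact:
    """Compression-only contact of femoral points against a tibial plane.

    A rigid-contact surrogate for the tibiofemoral articulation: each
    femoral point penetrating the plane (measured along the outward
    ``normal``) receives a restoring force ``stiffness * penetration``
    along the normal.
    """

    points: np.ndarray  # femur-local contact points (n, 3)
    plane_point: np.ndarray
    normal: np.ndarray  # outward (away from tibia), unit
    stiffness: float = 5000.0  # N/mm

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.plane_point = np.asarray(self.plane_point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        if self.stiffness <= 0:
            raise InvalidParameterError("contact stiffness must be > 0")

    def penetrations(self, transform) -> np.ndarray:
        T = np.asarray(transform, dtype=float)
        world = self.points @ T[:3, :3].T + T[:3, 3]
        gap = (world - self.plane_point) @ self.normal
        return np.maximum(-gap, 0.0)

    def energy(self, transform) -> float:
        p = self.penetrations(transform)
        return float(0.5 * self.stiffness * np.sum(p**2))


@dataclass
class Graft:
    """A graft: its generating spec, optional hex mesh and effective bundle."""

    spec: GraftSpec
    mesh: HexMesh | None = None
    bundle: LigamentBundle | None = None
    fixation_angle: float | None = None  # deg of knee flexion at fixation
    pretension: float | None = None  # N
    fixation_pose: object = None  # JointPose at which slack lengths were set


@dataclass
class KneeModel:
    """Assembled rigid-bone + spring-bundle knee model.

    ``variant`` is ``"RM"`` (healthy reference: native ACL, no graft),
    ``"SB"`` (one graft) or ``"DB"`` (two grafts, no native ACL).
    Ligament femoral attachments are femur-frame-local; tibial insertions
    are world (the tibia is the fixed body).
    """

    variant: str
    femur_frame: BodyFrame
    tibia_frame: BodyFrame
    ligaments: list = field(default_factory=list)
    grafts: list = field(default_factory=list)
    contacts: list = field(default_factory=list)
    femur_mesh: object = None
    tibia_mesh: object = None
    plan: object = None
    constants: dict = field(default_factory=lambda: {
        "meniscal_root_stiffness": MENISCAL_ROOT_STIFFNESS,
        "contact_pairs": [
            "femoral-cartilage/tibial-cartilage",
            "menisci/cartilage",
            "graft/bone-tunnel",
        ],
    })
    metadata: dict = field(default_factory=dict)

    ATTACHMENT_TOLERANCE = 2.0  # mm, max attachment-to-surface distance

    @property
    def active_bundles(self):
        out = list(self.ligaments)
        out.extend(g.bundle for g in self.grafts if g.bundle is not None)
        return out

    def bundle(self, name: str) -> LigamentBundle:
        for b in self.active_bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def femur_transform(self, pose: JointPose | None = None) -> np.ndarray:
        if pose is None:
            T = np.eye(4)
            T[:3, :3] = self.femur_frame.axes
            T[:3, 3] = self.femur_frame.origin
            return T
        return pose_to_transform(pose, self.tibia_frame)

    def validate(self) -> "KneeModel":
        if self.variant not in ("RM", "SB", "DB"):
            raise AssemblyError(f"unknown variant {self.variant!r}")
        names = [b.name for b in self.ligaments]
        if self.variant == "RM":
            if "ACL" not in names:
                raise AssemblyError("RM variant requires a native ACL bundle")
            if self.grafts:
                raise AssemblyError("RM variant must not carry a graft")
        else:
            expected = 1 if self.variant == "SB" else 2
            if len(self.grafts) != expected:
                raise AssemblyError(
                    f"{self.variant} variant requires {expected} graft(s), "
                    f"got {len(self.grafts)}"
                )
            if "ACL" in names:
                raise AssemblyError("ACLR variants replace the native ACL")
        self._check_attachments()
        return self

    def _check_attachments(self):
        T = self.femur_transform()
        for b in self.active_bundles:
            for mesh, pts in (
                (self.femur_mesh, b.origins @ T[:3, :3].T + T[:3, 3]),
                (self.tibia_mesh, b.insertions),
            ):
                if mesh is None:
                    continue
                d = _sdf.point_triangle_distance(pts, np.asarray(mesh.triangles))
                if d.max() > self.ATTACHMENT_TOLERANCE:
                    raise AssemblyError(
                        f"bundle {b.name!r} attachment {d.max():.2f} mm from "
                        f"the bone surface (> {self.ATTACHMENT_TOLERANCE} mm)"
                    )


def assemble_model(
    variant: str,
    femur_frame: BodyFrame,
    tibia_frame: BodyFrame,
    ligaments,
    grafts=(),
    contacts=(),
    femur_mesh=None,
    tibia_mesh=None,
    plan=None,
) -> KneeModel:
    """Build and validate a knee model for the requested variant.

    Ligament bundles with unresolved slack lengths are resolved at the
    assembly pose (their chord lengths become the reference lengths).
    """
    model = KneeModel(
        variant=variant,
        femur_frame=femur_frame,
        tibia_frame=tibia_frame,
        ligaments=list(ligaments),
        grafts=list(grafts),
        contacts=list(contacts),
        femur_mesh=femur_mesh,
        tibia_mesh=tibia_mesh,
        plan=plan,
    )
    T = model.femur_transform()
    for b in model.ligaments:
        if b.L_0 is None:
            b.resolve_slack_lengths(T)
    return model.validate()


# -- FEBio export -----------------------------------------------------------

def _spring_curve(per_spring_k, eps_l, L_0, n_points: int = 51):
    """Tabulated force-elongation curve for one discrete spring.

    Elongations span ``[0, 3 eps_l L_0]``; the branch junction at
    ``2 eps_l L_0`` is always a table node so the curve value there is
    exactly ``k eps_l``.
    """
    n_toe = (2 * (n_points - 1)) // 3 + 1
    e1 = np.linspace(0.0, 2 * eps_l * L_0, n_toe)
    e2 = np.linspace(2 * eps_l * L_0, 3 * eps_l * L_0, n_points - n_toe + 1)[1:]
    elong = np.concatenate([e1, e2])
    force = blankevoort_force(elong / L_0, per_spring_k, eps_l)
    return elong, np.atleast_1d(force)


def export_feb(model: KneeModel, path, n_curve_points: int = 51):
    """Write the model as FEBio 3.0 ``.feb`` XML.

    Rigid bones become shell-triangle domains with rigid materials,
    ligament bundles become discrete nonlinear-spring elements with
    tabulated force-displacement curves, and graft hex domains carry their
    harvest-site material tag as a placeholder.  Continuum tissues
    (cartilage, menisci) appear only as named contact-pair placeholders.
    """
    root = etree.Element("febio_spec", version="3.0")
    etree.SubElement(root, "Module", type="solid")

    material = etree.SubElement(root, "Material")
    mats = []
    for name in ("femur", "tibia"):
        m = etree.SubElement(material, "material", id=str(len(mats) + 1), name=name,
                             type="rigid body")
        etree.SubElement(m, "density").text = "1e-9"
        mats.append(name)
    for gi, g in enumerate(model.grafts):
        m = etree.SubElement(material, "material", id=str(len(mats) + 1),
                             name=f"graft-{gi + 1}", type="uncoupled solid mixture")
        etree.SubElement(m, "harvest_site").text = g.spec.material
        mats.append(f"graft-{gi + 1}")

    mesh = etree.SubElement(root, "Mesh")
    node_block = etree.SubElement(mesh, "Nodes", name="all")
    coords: list[np.ndarray] = []

    def add_nodes(arr):
        start = len(coords) + 1
        coords.extend(np.atleast_2d(arr))
        return np.arange(start, start + len(np.atleast_2d(arr)))

    body_elems = []
    Tf = model.femur_transform()
    for name, m3, transform in (
        ("femur", model.femur_mesh, Tf),
        ("tibia", model.tibia_mesh, np.eye(4)),
    ):
        if m3 is None:
            continue
        verts = np.asarray(m3.vertices) @ transform[:3, :3].T + transform[:3, 3]
        ids = add_nodes(verts)
        body_elems.append((name, "tri3", ids[np.asarray(m3.faces)]))
    for gi, g in enumerate(model.grafts):
        if g.mesh is None:
            continue
        ids = add_nodes(g.mesh.nodes)
        body_elems.append((f"graft-{gi + 1}", "hex8", ids[g.mesh.elements]))

    discrete_sets = []
    for b in model.active_bundles:
        if b.L_0 is None:
            raise ExportError(f"bundle {b.name!r} has unresolved slack lengths")
        o_ids = add_nodes(b.origins @ Tf[:3, :3].T + Tf[:3, 3])
        i_ids = add_nodes(b.insertions)
        discrete_sets.append((b, o_ids, i_ids))

    for nid, p in enumerate(coords, start=1):
        etree.SubElement(node_block, "node", id=str(nid)).text = (
            f"{p[0]:.12g},{p[1]:.12g},{p[2]:.12g}"
        )
    for name, etype, conn in body_elems:
        mat_id = str(mats.index(name) + 1) if name in mats else "1"
        eb = etree.SubElement(mesh, "Elements", type=etype, name=name, mat=mat_id)
        for eid, row in enumerate(conn, start=1):
            etree.SubElement(eb, "elem", id=str(eid)).text = ",".join(map(str, row))
    for b, o_ids, i_ids in discrete_sets:
        ds = etree.SubElement(mesh, "DiscreteSet", name=b.name)
        for a, c in zip(o_ids, i_ids):
            etree.SubElement(ds, "delem").text = f"{a},{c}"

    domains = etree.SubElement(root, "MeshDomains")
    for name, etype, _ in body_elems:
        tag = "ShellDomain" if etype == "tri3" else "SolidDomain"
        etree.SubElement(domains, tag, name=name, mat=name if name in mats else "femur")

    discrete = etree.SubElement(root, "Discrete")
    loaddata = etree.SubElement(root, "LoadData")
    for di, (b, _, _) in enumerate(discrete_sets, start=1):
        dm = etree.SubElement(discrete, "discrete_material", id=str(di), name=b.name,
                              type="nonlinear spring")
        etree.SubElement(dm, "force", lc=str(di)).text = "1"
        etree.SubElement(discrete, "discrete", dmat=str(di), discrete_set=b.name)
        lc = etree.SubElement(loaddata, "load_controller", id=str(di), type="loadcurve")
        etree.SubElement(lc, "interpolate").text = "LINEAR"
        pts = etree.SubElement(lc, "points")
        L0 = float(np.mean(b.L_0))
        elong, force = _spring_curve(b.per_spring_k, b.law.eps_l, L0, n_curve_points)
        for e, f in zip(elong, force):
            etree.SubElement(pts, "point").text = f"{e:.12g},{f:.12g}"

    contact = etree.SubElement(root, "Contact")
    for pair in model.constants.get("contact_pairs", []):
        etree.SubElement(contact, "contact", type="sliding-elastic", name=pair,
                         surface_pair=pair)

    step_block = etree.SubElement(root, "Step")
    steps = [("pretension", g) for g in model.grafts] or []
    for sname, g in steps:
        st = etree.SubElement(step_block, "step", name=sname)
        ctrl = etree.SubElement(st, "Control")
        etree.SubElement(ctrl, "analysis").text = "STATIC"
        bc = etree.SubElement(st, "Boundary")
        etree.SubElement(bc, "bc", type="rigid_fixed", body="tibia")
        load = etree.SubElement(st, "Loads")
        p = etree.SubElement(load, "surface_load", type="pressure",
                             surface="graft-bottom")
        etree.SubElement(p, "pressure").text = (
            f"{(g.pretension or 0.0) / g.spec.section_area:.12g}"
        )
    st = etree.SubElement(step_block, "step", name="lachman")
    ctrl = etree.SubElement(st, "Control")
    etree.SubElement(ctrl, "analysis").text = "STATIC"
    bc = etree.SubElement(st, "Boundary")
    etree.SubElement(bc, "bc", type="rigid_fixed", body="tibia")
    etree.SubElement(bc, "bc", type="rigid_rotation_fixed", body="femur", dof="Rz")

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")
    # fail early if the written file does not re-parse
    etree.parse(str(path))


def read_feb(path):
    """Parse a ``.feb`` file written by :func:`export_feb`.

    Returns a dict with node coordinates, element blocks, discrete sets and
    tabulated spring curves -- the structural content used by round-trip
    checks.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    nodes = {}
    for n in root.findall("./Mesh/Nodes/node"):
        nodes[int(n.get("id"))] = np.array([float(x) for x in n.text.split(",")])
    ids = sorted(nodes)
    coords = np.array([nodes[i] for i in ids])
    elements = {}
    for eb in root.findall("./Mesh/Elements"):
        conn = [[int(x) for x in e.text.split(",")] for e in eb.findall("elem")]
        elements[eb.get("name")] = {"type": eb.get("type"), "conn": np.array(conn, dtype=int)}
    dsets = {}
    for ds in root.findall("./Mesh/DiscreteSet"):
        pairs = [[int(x) for x in d.text.split(",")] for d in ds.findall("delem")]
        dsets[ds.get("name")] = np.array(pairs, dtype=int)
    curves = {}
    for dm in root.findall("./Discrete/discrete_material"):
        lc_id = dm.find("force").get("lc")
        lc = root.find(f"./LoadData/load_controller[@id='{lc_id}']")
        pts = np.array(
            [[float(x) for x in p.text.split(",")] for p in lc.findall("./points/point")]
        )
        curves[dm.get("name")] = pts
    return {"nodes": coords, "node_ids": np.array(ids), "elements": elements,
            "discrete_sets": dsets, "spring_curves": curves}


def export_vtk(model: KneeModel, directory):
    """Write one legacy VTK file per rigid body and graft.

    Returns the list of written file paths.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    Tf = model.femur_transform()
    for name, m3, transform in (
        ("femur", model.femur_mesh, Tf),
        ("tibia", model.tibia_mesh, np.eye(4)),
    ):
        if m3 is None:
            continue
        p = directory / f"{name}.vtk"
        verts = np.asarray(m3.vertices) @ transform[:3, :3].T + transform[:3, 3]
        _vtk.write_vtk(p, verts, np.asarray(m3.faces), 5, title=name)
        written.append(p)
    for gi, g in enumerate(model.grafts):
        if g.mesh is None:
            continue
        p = directory / f"graft_{gi + 1}.vtk"
        if g.spec.element_type == "tet":
            nodes, tets = g.mesh.to_tets()
            _vtk.write_vtk(p, nodes, tets, 10, title=f"graft {gi + 1}")
        else:
            _vtk.write_vtk(p, g.mesh.nodes, g.mesh.elements, 12, title=f"graft {gi + 1}")
        written.append(p)
    return written
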