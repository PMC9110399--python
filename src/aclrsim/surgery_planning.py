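"""Virtual tunnel planning and drilling for ACL reconstruction.

A tunnel is defined by four anatomical landmarks: the tibial tunnel entry
and footprint, and the femoral footprint and tunnel exit.  The path is a
composite curve -- a straight tibial segment, a cubic blend (a NURBS with
uniform weights) spanning the intra-articular space, and a straight
femoral segment -- with tangent-continuous joins.  Drilling subtracts a
capped cylinder swept along a straight segment from the bone mesh.

Because no exact CSG backend is assumed, the boolean is evaluated on a
signed-distance grid (exact analytic cylinder distance, mesh distance for
the bone) and the drilled surface is extracted with marching cubes; the
removed volume converges to ``pi r^2 * thickness`` as the grid is refined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from . import _sdf
from .errors import (
    DrillingError,
    InvalidLandmarksError,
    InvalidParameterError,
    OsseousWallViolationError,
)

__all__ = [
    "LandmarkSet",
    "TunnelPath",
    "Tunnel",
    "SurgeryPlan",
    "build_path",
    "drill_tunnel",
    "make_plan",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Four tunnel-defining landmarks (mm, world frame).

    ``tibia_entry`` and ``tibia_footprint`` bound the tibial bone segment;
    ``femur_footprint`` and ``femur_exit`` bound the femoral segment.
    """

    tibia_entry: np.ndarray
    tibia_footprint: np.ndarray
    femur_footprint: np.ndarray
    femur_exit: np.ndarray

    def __post_init__(self):
        for name in ("tibia_entry", "tibia_footprint", "femur_footprint", "femur_exit"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        pts = self.as_array()
        for i in range(4):
            for j in range(i + 1, 4):
                if np.linalg.norm(pts[i] - pts[j]) < 1e-9:
                    raise InvalidLandmarksError("landmarks must be pairwise distinct")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tibia_entry, self.tibia_footprint, self.femur_footprint, self.femur_exit]
        )


class TunnelPath:
    """Composite tunnel path through four landmarks.

    Segments: straight ``tibia_entry -> tibia_footprint``, cubic blend
    ``tibia_footprint -> femur_footprint`` whose end tangents match the
    straight directions, straight ``femur_footprint -> femur_exit``.
    Parameterized by arc length.
    """

    _SAMPLES_PER_PIECE = 256

    def __init__(self, landmarks: LandmarkSet):
        self.landmarks = landmarks
        a, b, c, d = landmarks.as_array()
        d1 = b - a
        d2 = d - c
        n1 = np.linalg.norm(d1)
        n2 = np.linalg.norm(d2)
        if n1 < 1e-9 or n2 < 1e-9:
            raise InvalidLandmarksError("straight tunnel segments are degenerate")
        h = np.linalg.norm(c - b)
        # interior control points along the straight directions, 1/3 of the
        # footprint-to-footprint distance away: guarantees C1 joins
        self.control_points = np.array([b, b + d1 / n1 * (h / 3.0), c - d2 / n2 * (h / 3.0), c])
        self._pieces = []
        for kind, args in (
            ("line", (a, b)),
            ("bezier", tuple(self.control_points)),
            ("line", (c, d)),
        ):
            self._pieces.append((kind, args))
        self._build_tables()

    # -- evaluation ---------------------------------------------------------
    @staticmethod
    def _eval_piece(kind, args, u):
        u = np.asarray(u, dtype=float)[..., None]
        if kind == "line":
            p0, p1 = args
            return (1 - u) * p0 + u * p1
        p0, p1, p2, p3 = args
        return (
            (1 - u) ** 3 * p0
            + 3 * (1 - u) ** 2 * u * p1
            + 3 * (1 - u) * u**2 * p2
            + u**3 * p3
        )

    def _build_tables(self):
        self._tables = []
        lengths = []
        for kind, args in self._pieces:
            u = np.linspace(0.0, 1.0, self._SAMPLES_PER_PIECE)
            pts = self._eval_piece(kind, args, u)
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            self._tables.append((u, cum))
            lengths.append(cum[-1])
        self._piece_lengths = np.array(lengths)
        self._cum_lengths = np.concatenate([[0.0], np.cumsum(self._piece_lengths)])

    @property
    def length(self) -> float:
        """Total arc length (mm)."""
        return float(self._cum_lengths[-1])

    def point_at(self, s):
        """Point(s) at arc length ``s`` from the tibial entry."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        s = np.clip(s, 0.0, self.length)
        out = np.empty((len(s), 3))
        idx = np.clip(np.searchsorted(self._cum_lengths, s, side="right") - 1, 0, 2)
        for i in range(3):
            m = idx == i
            if not m.any():
                continue
            u_tab, cum = self._tables[i]
            local = s[m] - self._cum_lengths[i]
            u = np.interp(local, cum, u_tab)
            out[m] = self._eval_piece(*self._pieces[i], u)
        return out if out.shape[0] > 1 else out[0]

    def sample(self, n: int = 200) -> np.ndarray:
        """``n`` points equally spaced in arc length along the path."""
        return np.atleast_2d(self.point_at(np.linspace(0.0, self.length, n)))

    def tangent_at(self, s, h: float = 1e-4) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        a = self.point_at(max(s - h, 0.0))
        b = self.point_at(min(s + h, self.length))
        t = np.asarray(b) - np.asarray(a)
        return t / np.linalg.norm(t)

    def straight_segment(self, segment: str):
        """Endpoints of the tibial or femoral straight segment."""
        if segment == "tibial":
            return self.landmarks.tibia_entry, self.landmarks.tibia_footprint
        if segment == "femoral":
            return self.landmarks.femur_footprint, self.landmarks.femur_exit
        raise InvalidParameterError(f"segment must be 'tibial' or 'femoral', got {segment!r}")

    def blend_curvature_radius(self, n: int = 200) -> float:
        """Minimum osculating-circle radius along the blend (mm)."""
        u = np.linspace(0.0, 1.0, n)
        p = self._eval_piece(*self._pieces[1], u)
        d1 = np.gradient(p, u, axis=0)
        d2 = np.gradient(d1, u, axis=0)
        num = np.linalg.norm(np.cross(d1, d2), axis=1)
        den = np.linalg.norm(d1, axis=1) ** 3
        kappa = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        kmax = kappa.max()
        return float(np.inf) if kmax < 1e-12 else float(1.0 / kmax)


def build_path(landmarks: LandmarkSet) -> TunnelPath:
    """Construct the composite tunnel path through the four landmarks."""
    return TunnelPath(landmarks)


@dataclass
class Tunnel:
    path: TunnelPath
    radius: float
    label: str = "AM"

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("tunnel radius must be > 0")


@dataclass
class SurgeryPlan:
    """A validated set of tunnels for the chosen technique (SB or DB)."""

    technique: str
    tunnels: list[Tunnel] = field(default_factory=list)

    def __post_init__(self):
        if self.technique not in ("SB", "DB"):
            raise InvalidParameterError("technique must be 'SB' or 'DB'")


def make_plan(technique: str, landmark_sets, radii, labels=None) -> SurgeryPlan:
    """Build and validate a surgery plan.

    SB takes one landmark set, DB two.  For DB the two swept tunnel
    cylinders must not intersect (the osseous wall between them must
    survive); the check uses densely sampled path-to-path distances.
    """
    if technique not in ("SB", "DB"):
        raise InvalidParameterError("technique must be 'SB' or 'DB'")
    landmark_sets = list(landmark_sets)
    radii = [float(r) for r in np.atleast_1d(radii)]
    expected = 1 if technique == "SB" else 2
    if len(landmark_sets) != expected or len(radii) != expected:
        raise InvalidParameterError(
            f"{technique} needs {expected} landmark set(s) and radius value(s)"
        )
    if labels is None:
        labels = ["AM"] if technique == "SB" else ["AM", "PL"]
    tunnels = [
        Tunnel(build_path(ls), r, lab) for ls, r, lab in zip(landmark_sets, radii, labels)
    ]
    if technique == "DB":
        a = tunnels[0].path.sample(400)
        b = tunnels[1].path.sample(400)
        gap = cKDTree(a).query(b)[0].min() - (tunnels[0].radius + tunnels[1].radius)
        if gap <= 0:
            raise OsseousWallViolationError(
                f"DB tunnels intersect (clearance {gap:.3f} mm <= 0)"
            )
    return SurgeryPlan(technique, tunnels)


# -- drilling ---------------------------------------------------------------

def _axis_crossings(p0, p1, mesh, n=512):
    """In/out transitions of the (extended) axis segment with the bone."""
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None] + t[:, None] * (p1 - p0)[None]
    inside = _sdf.points_inside(pts, np.asarray(mesh.triangles))
    return t, pts, inside


def _check_wall(mesh, p0, p1, radius):
    """Require bone to extend laterally beyond ``radius`` around the axis."""
    tri = np.asarray(mesh.triangles)
    t, pts, inside = _axis_crossings(p0, p1, mesh)
    if not inside.any():
        return False  # axis misses the bone entirely
    seg_len = np.linalg.norm(p1 - p0)
    depth_margin = max(radius, 1e-3) / seg_len
    # distance (in t) from each axis sample to the nearest in/out transition
    trans = np.where(np.diff(inside.astype(int)) != 0)[0]
    trans_t = 0.5 * (t[trans] + t[trans + 1]) if len(trans) else np.array([])
    axis = (p1 - p0) / seg_len
    # two perpendicular directions
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    interior = inside.copy()
    if len(trans_t):
        near = np.min(np.abs(t[:, None] - trans_t[None, :]), axis=1) < depth_margin
        interior &= ~near
    stations = pts[interior][:: max(1, interior.sum() // 24)]
    if len(stations) == 0:
        raise DrillingError(
            "tunnel radius is too large relative to the bone thickness along the axis"
        )
    angles = np.linspace(0.0, 2 * np.pi, 16, endpoint=False)
    dirs = np.cos(angles)[:, None] * u[None] + np.sin(angles)[:, None] * v[None]
    for p in stations:
        for d in dirs:
            hits = _sdf.ray_hits(p[None], d, tri)[0]
            if len(hits) == 0 or hits[0] < radius:
                raise DrillingError(
                    f"tunnel wall destroyed: lateral bone cover "
                    f"{hits[0] if len(hits) else 0.0:.3f} mm < radius {radius} mm"
                )
    return True


def drill_tunnel(
    bone: trimesh.Trimesh,
    path: TunnelPath,
    segment: str,
    radius: float,
    pitch: float | None = None,
    extension: float = 0.10,
) -> trimesh.Trimesh:
    """Subtract a capped drilling cylinder from the bone mesh.

    The cylinder sweeps the requested straight segment of the path,
    extended by ``extension`` of its length beyond both ends so its caps
    clear the bone faces.  The difference is evaluated on a signed-distance
    grid (``pitch`` defaults to ``radius / 8``) and re-surfaced with
    marching cubes; the result is watertight or a :class:`DrillingError`
    is raised.  A cylinder that misses the bone leaves it unchanged with a
    warning.
    """
    if radius <= 0:
        raise InvalidParameterError("drill radius must be > 0")
    p0, p1 = path.straight_segment(segment)
    d = p1 - p0
    p0e = p0 - extension * d
    p1e = p1 + extension * d

    # fast reject: does the swept cylinder reach the bone at all?
    verts = np.asarray(bone.vertices)
    if _sdf.capped_cylinder_sdf(verts, p0e, p1e, radius).max() < -1e-9:
        t, _, inside = _axis_crossings(p0e, p1e, bone)
        if not inside.any():
            warnings.warn("drilling cylinder does not intersect the bone; mesh unchanged")
            return bone.copy()

    if not _check_wall(bone, p0e, p1e, radius):
        warnings.warn("drilling cylinder does not intersect the bone; mesh unchanged")
        return bone.copy()

    if pitch is None:
        pitch = radius / 8.0
    # offset the grid by an irrational fraction of the pitch so mesh faces of
    # axis-aligned fixtures never coincide with grid points (ambiguous sign)
    lo = bone.bounds[0] - 3 * pitch - 0.31830988618 * pitch
    hi = bone.bounds[1] + 3 * pitch
    ns = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    if np.prod(ns.astype(float)) > 2.5e7:
        raise DrillingError(
            "signed-distance grid would exceed 25M voxels; increase pitch"
        )
    xs = [lo[i] + np.arange(ns[i]) * pitch for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    phi_bone = _sdf.signed_distance(pts, bone)
    phi_cyl = _sdf.capped_cylinder_sdf(pts, p0e, p1e, radius)
    phi = np.minimum(phi_bone, -phi_cyl).reshape(ns)

    if phi.max() <= 0:
        raise DrillingError("drilling removed the entire bone")
    mc_verts, mc_faces, _, _ = marching_cubes(
        phi, level=0.0, spacing=(pitch,) * 3, allow_degenerate=False
    )
    out = trimesh.Trimesh(vertices=mc_verts + lo, faces=mc_faces, process=True)
    out.fix_normals()
    if out.volume < 0:
        out.invert()
    if not out.is_watertight:
        raise DrillingError("drilled mesh is not watertight (marching-cubes surface open)")
    return out
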