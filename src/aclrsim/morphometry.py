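"""Ligament cross-section morphometry from segmented surface meshes.

A segmented ligament mesh is reduced to a mean cross-sectional area by
slicing it with planes normal to its principal axis (the leading PCA
eigenvector of the vertex cloud).  Planes are spaced one unit (1 mm)
apart over the length of the bounding-box main diagonal, centered on the
mesh centroid; each plane section's closed contours are measured as planar
polygons and the retained stations are averaged.  Multiplying the mean
area by a Young's modulus gives the bundle stiffness ``k = E * A`` used by
the spring ligament model.

Stations whose sections are empty or open (end caps, segmentation holes)
are dropped rather than repaired; a 1e-6 mm^2 floor filters numerical
slivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np
import shapely.geometry
import trimesh

from .errors import DegenerateShapeWarning, EmptyProfileError, InvalidParameterError
from .ligament_mechanics import stiffness_from_EA

__all__ = [
    "CrossSectionProfile",
    "principal_axis",
    "slice_areas",
    "mean_cross_section_area",
    "estimate_ligament_stiffness",
]

_MIN_STATION_AREA = 1e-6  # mm^2; below this a contour is a numerical sliver


def _section_area(path2d) -> float:
    """Planar area of a section's closed contours (open contours dropped).

    Nested contours are combined even-odd (symmetric difference), so
    disjoint components sum and internal voids subtract.
    """
    polys = []
    for loop in path2d.discrete:
        if len(loop) < 3 or np.linalg.norm(loop[0] - loop[-1]) > 1e-8:
            continue  # open contour: end cap or segmentation hole
        p = shapely.geometry.Polygon(loop)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area >= _MIN_STATION_AREA:
            polys.append(p)
    if not polys:
        return 0.0
    return float(reduce(lambda a, b: a.symmetric_difference(b), polys).area)


@dataclass
class CrossSectionProfile:
    """Per-station section areas of a mesh along an axis."""

    axis: np.ndarray
    stations: np.ndarray  # signed offsets from the centroid along axis, mm
    areas: np.ndarray  # mm^2, one per retained station

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas))

    def write(self, path):
        """Write (station, area) pairs as delimited text."""
        header = "station_mm\tarea_mm2"
        np.savetxt(path, np.column_stack([self.stations, self.areas]), header=header, delimiter="\t")


def principal_axis(mesh: trimesh.Trimesh, area_weighted: bool = False) -> np.ndarray:
    """Leading PCA axis of the mesh vertices, as a unit vector.

    The sign is fixed so the component of largest magnitude is positive.
    If the leading eigenvalue is within 1% of the second, the shape has no
    well-separated long axis and a :class:`DegenerateShapeWarning` is
    emitted (the axis is still returned).

    ``area_weighted=True`` weights vertices by a third of the summed area
    of their incident faces, reducing sensitivity to uneven tessellation.
    """
    verts = np.asarray(mesh.vertices, dtype=float)
    if len(verts) < 4:
        raise InvalidParameterError("need at least 4 vertices for a principal axis")
    if area_weighted:
        w = np.zeros(len(verts))
        np.add.at(w, np.asarray(mesh.faces).ravel(), np.repeat(mesh.area_faces / 3.0, 3))
        w = w / w.sum()
        mean = w @ verts
        centered = verts - mean
        cov = (centered * w[:, None]).T @ centered
    else:
        centered = verts - verts.mean(axis=0)
        cov = centered.T @ centered / len(verts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] <= 0:
        raise InvalidParameterError("vertices are coplanar or degenerate")
    if evals[1] > 0.99 * evals[2]:
        warnings.warn(
            "mesh has no well-separated principal axis "
            f"(leading eigenvalues {evals[2]:.4g} vs {evals[1]:.4g})",
            DegenerateShapeWarning,
            stacklevel=2,
        )
    axis = evecs[:, 2]
    i = int(np.argmax(np.abs(axis)))
    if axis[i] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def slice_areas(mesh: trimesh.Trimesh, axis, step: float = 1.0) -> CrossSectionProfile:
    """Section the mesh with planes normal to ``axis`` spaced ``step`` mm.

    The station range spans the length of the bounding-box main diagonal,
    centered on the mesh centroid, so some stations necessarily miss the
    mesh; those (and stations with only open contours) are dropped.  The
    area at each retained station is the summed area of its closed planar
    contours, so disjoint components are handled naturally.
    """
    if step <= 0:
        raise InvalidParameterError("slice step must be > 0")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    diagonal = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    half = diagonal / 2.0
    heights = np.arange(-half, half + 0.5 * step, step)
    centroid = mesh.vertices.mean(axis=0)
    sections = mesh.section_multiplane(
        plane_origin=centroid, plane_normal=axis, heights=heights
    )
    stations, areas = [], []
    for h, sec in zip(heights, sections):
        if sec is None:
            continue
        area = _section_area(sec)
        if area < _MIN_STATION_AREA:
            continue
        stations.append(h)
        areas.append(area)
    if not areas:
        raise EmptyProfileError("no plane station produced a closed contour")
    return CrossSectionProfile(axis=axis, stations=np.array(stations), areas=np.array(areas))


def mean_cross_section_area(mesh: trimesh.Trimesh, step: float = 1.0, area_weighted: bool = False) -> float:
    """Mean section area (mm^2) along the mesh's principal axis."""
    axis = principal_axis(mesh, area_weighted=area_weighted)
    return slice_areas(mesh, axis, step=step).mean_area


def estimate_ligament_stiffness(mesh: trimesh.Trimesh, E: float, step: float = 1.0) -> float:
    """Bundle stiffness ``k = E * mean_cross_section_area(mesh)`` in N."""
    if E <= 0:
        raise InvalidParameterError("Young's modulus must be > 0")
    return stiffness_from_EA(E, mean_cross_section_area(mesh, step=step))
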