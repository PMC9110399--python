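"""Signed-distance and ray utilities for low-polygon bone meshes.

Small, self-contained geometric kernels used by the tunnel-drilling
level-set boolean: exact point-triangle distances, parity-based
inside/outside classification, and ray-mesh intersection.  All routines
are vectorized over points and triangles and intended for the low-face-
count bone meshes this toolkit drills (costs scale as points x faces).
"""

from __future__ import annotations

import numpy as np

_CHUNK = 65536


def point_triangle_distance(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the nearest triangle.

    ``points`` is (N, 3); ``triangles`` is (F, 3, 3).  Returns (N,).
    Classic closest-point-on-triangle region tests (Ericson), broadcast
    over all point/triangle pairs in chunks.
    """
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    out = np.empty(len(points))
    for lo in range(0, len(points), _CHUNK):
        out[lo : lo + _CHUNK] = _ptd_chunk(points[lo : lo + _CHUNK], triangles)
    return out


def _ptd_chunk(P, tri):
    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = (B - A)[None, :, :]  # (1,F,3)
    ac = (C - A)[None, :, :]
    ap = P[:, None, :] - A[None, :, :]  # (N,F,3)

    d1 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ac, ap)[0], ap)
    bp = P[:, None, :] - B[None, :, :]
    d3 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ac, bp)[0], bp)
    cp = P[:, None, :] - C[None, :, :]
    d5 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("nfk,nfk->nf", np.broadcast_arrays(ac, cp)[0], cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    # default: interior projection via barycentric coordinates
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest = A[None] + v[..., None] * ab + w[..., None] * ac

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest = np.where(m[..., None], A[None] + 0.0 * closest, closest)
    m = (d3 >= 0) & (d4 <= d3)
    closest = np.where(m[..., None], np.broadcast_to(B[None], closest.shape), closest)
    m = (d6 >= 0) & (d5 <= d6)
    closest = np.where(m[..., None], np.broadcast_to(C[None], closest.shape), closest)

    # edge AB
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) < 1e-300, 0.0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3))
    cand = A[None] + np.clip(t, 0, 1)[..., None] * ab
    closest = np.where(m[..., None], cand, closest)
    # edge AC
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6)
    cand = A[None] + np.clip(t, 0, 1)[..., None] * ac
    closest = np.where(m[..., None], cand, closest)
    # edge BC
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    t = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1.0, (d4 - d3) + (d5 - d6))
    cand = B[None] + np.clip(t, 0, 1)[..., None] * (C - B)[None]
    closest = np.where(m[..., None], cand, closest)

    d = np.linalg.norm(P[:, None, :] - closest, axis=-1)
    return d.min(axis=1)


def ray_hits(origins: np.ndarray, direction, triangles: np.ndarray):
    """Moller-Trumbore ray/triangle intersection distances.

    Single shared ``direction`` for all ``origins``; returns a list of
    sorted positive hit distances per origin.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    A = triangles[:, 0]
    e1 = triangles[:, 1] - A
    e2 = triangles[:, 2] - A
    h = np.cross(direction, e2)  # (F,3)
    a = np.einsum("fk,fk->f", e1, h)
    ok = np.abs(a) > 1e-12
    results = []
    inv_a = np.where(ok, 1.0 / np.where(a == 0, 1.0, a), 0.0)
    for o in origins:
        s = o - A
        u = np.einsum("fk,fk->f", s, h) * inv_a
        q = np.cross(s, e1)
        v = np.einsum("k,fk->f", direction, q) * inv_a
        t = np.einsum("fk,fk->f", e2, q) * inv_a
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-9)
        results.append(np.sort(t[hit]))
    return results


def points_inside(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Parity (crossing-number) inside test for a watertight mesh.

    A deterministic, slightly irrational ray direction avoids edge/vertex
    grazing for axis-aligned fixture geometry.
    """
    direction = np.array([0.5773502691896258, 0.5773502691896258, 0.5773502691896258])
    direction += np.array([1.23e-4, -2.71e-4, 3.14e-4])
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.zeros(len(points), dtype=bool)
    for lo in range(0, len(points), _CHUNK):
        chunk = points[lo : lo + _CHUNK]
        counts = _crossing_counts(chunk, direction, triangles)
        inside[lo : lo + _CHUNK] = counts % 2 == 1
    return inside


def _crossing_counts(P, direction, tri):
    A = tri[:, 0]
    e1 = tri[:, 1] - A
    e2 = tri[:, 2] - A
    h = np.cross(direction, e2)
    a = np.einsum("fk,fk->f", e1, h)
    ok = np.abs(a) > 1e-12
    inv_a = np.where(ok, 1.0 / np.where(a == 0, 1.0, a), 0.0)
    s = P[:, None, :] - A[None, :, :]  # (N,F,3)
    u = np.einsum("nfk,fk->nf", s, h) * inv_a[None]
    q = np.cross(s, e1[None, :, :])
    v = np.einsum("k,nfk->nf", direction, q) * inv_a[None]
    t = np.einsum("fk,nfk->nf", e2, q) * inv_a[None]
    hit = ok[None] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
    return hit.sum(axis=1)


def signed_distance(points: np.ndarray, mesh) -> np.ndarray:
    """Signed distance to a watertight mesh: positive inside."""
    tri = np.asarray(mesh.triangles, dtype=float)
    d = point_triangle_distance(points, tri)
    sign = np.where(points_inside(points, tri), 1.0, -1.0)
    return sign * d


def capped_cylinder_sdf(points: np.ndarray, p0, p1, radius: float) -> np.ndarray:
    """Exact signed distance to a capped cylinder (positive inside)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    h = np.linalg.norm(axis)
    axis = axis / h
    rel = np.asarray(points, dtype=float) - p0
    z = rel @ axis
    radial = np.linalg.norm(rel - z[:, None] * axis[None, :], axis=1)
    dr = radial - radius  # >0 outside laterally
    dz = np.maximum(-z, z - h)  # >0 outside axially
    outside = np.sqrt(np.maximum(dr, 0.0) ** 2 + np.maximum(dz, 0.0) ** 2)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return -(outside + inside)  # flip: positive inside
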