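"""Mesh geometry kernels: containment, ray casting, closest-point queries.

Small vectorized brute-force implementations (meshes in this package are a
few thousand triangles, so spatial indexing is unnecessary).
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = [
    "winding_contains",
    "ray_mesh_farthest_hits",
    "closest_point_on_mesh",
]


def winding_contains(mesh: trimesh.Trimesh, points: np.ndarray,
                     chunk: int = 512) -> np.ndarray:
    """Generalized winding number containment test for a closed mesh."""
    points = np.atleast_2d(np.asarray(points, float))
    tri = np.asarray(mesh.vertices[mesh.faces], float)  # (n_tri, 3, 3)
    inside = np.empty(len(points), bool)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        y = tri[None, :, :, :] - p[:, None, None, :]
        y1, y2, y3 = y[:, :, 0], y[:, :, 1], y[:, :, 2]
        l1 = np.linalg.norm(y1, axis=-1)
        l2 = np.linalg.norm(y2, axis=-1)
        l3 = np.linalg.norm(y3, axis=-1)
        triple = np.einsum("...i,...i->...", np.cross(y1, y2), y3)
        ss = (
            l1 * l2 * l3
            + np.einsum("...i,...i->...", y1, y2) * l3
            + np.einsum("...i,...i->...", y1, y3) * l2
            + np.einsum("...i,...i->...", y2, y3) * l1
        )
        omega = 2.0 * np.arctan2(triple, ss).sum(axis=1)  # total solid angle
        inside[s:s + chunk] = np.abs(omega) > 2.0 * np.pi  # ~4 pi inside, ~0 outside
    return inside


def ray_mesh_farthest_hits(mesh: trimesh.Trimesh, origin: np.ndarray,
                           directions: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Farthest intersection of rays from a common origin with the mesh.

    Moeller-Trumbore over all triangles; raises if any ray misses.
    """
    origin = np.asarray(origin, float)
    directions = np.atleast_2d(np.asarray(directions, float))
    tri = np.asarray(mesh.vertices[mesh.faces], float)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    out = np.empty((len(directions), 3))
    for i, d in enumerate(directions):
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = origin - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1 + 1e-10) & (t > eps)
        if not hit.any():
            raise ValueError("ray does not intersect the mesh")
        out[i] = origin + d * t[hit].max()
    return out


def closest_point_on_mesh(mesh: trimesh.Trimesh, points: np.ndarray):
    """Closest points on a triangle mesh (face/edge/vertex cases handled).

    Returns ``(closest (n, 3), distance (n,), tri_index (n,), bary (n, 3))``.
    Brute force over triangles using trimesh's per-pair closest-point kernel.
    """
    points = np.atleast_2d(np.asarray(points, float))
    tri = np.asarray(mesh.vertices[mesh.faces], float)
    n_pts = len(points)
    closest = np.empty((n_pts, 3))
    dist = np.empty(n_pts)
    tri_idx = np.empty(n_pts, int)
    bary = np.empty((n_pts, 3))
    for i, p in enumerate(points):
        cp = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        d2 = np.einsum("ij,ij->i", cp - p, cp - p)
        j = int(np.argmin(d2))
        closest[i] = cp[j]
        dist[i] = float(np.sqrt(d2[j]))
        tri_idx[i] = j
        bary[i] = trimesh.triangles.points_to_barycentric(tri[j:j + 1], cp[j:j + 1])[0]
    return closest, dist, tri_idx, bary
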