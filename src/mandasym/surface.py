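"""Exact closest-point queries on triangle surfaces.

This is the numerical core of the point-correspondence step: every vertex of
the reference hemimandible is mapped to the exactly closest point on the
mirrored contralateral surface.  Candidate triangles are found with a
k-d tree over triangle centroids; exactness is guaranteed by widening the
search radius by the largest triangle circumradius, so the true nearest
triangle is always among the candidates.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_mesh", "closest_point_brute_force", "point_triangle_closest"]


def point_triangle_closest(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point (paired, vectorized).

    ``points``: (n, 3); ``triangles``: (n, 3, 3).  Projects onto the triangle
    plane; if the projection falls outside, the closest point lies on an
    edge, so the minimum over the three clamped edge projections is taken.
    """
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn < 1e-300, 1.0, nn)

    ap = points - a
    # barycentric coordinates of the in-plane projection
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)

    result = a + v[:, None] * ab + w[:, None] * ac  # in-plane projection

    # edge fallback where the projection is outside the triangle
    out = ~inside
    if np.any(out):
        p_out = points[out]
        best_d2 = np.full(p_out.shape[0], np.inf)
        best_q = np.zeros_like(p_out)
        for e0, e1 in ((a[out], b[out]), (b[out], c[out]), (c[out], a[out])):
            d = e1 - e0
            dd = np.einsum("ij,ij->i", d, d)
            t = np.einsum("ij,ij->i", p_out - e0, d) / np.where(dd < 1e-300, 1.0, dd)
            t = np.clip(t, 0.0, 1.0)
            q = e0 + t[:, None] * d
            d2 = np.einsum("ij,ij->i", p_out - q, p_out - q)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            best_q[better] = q[better]
        result[out] = best_q
    return result


class SurfaceLocator:
    """Reusable exact nearest-point structure for one triangle mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise ValueError("mesh has no faces")
        self.triangles = mesh.triangles.view(np.ndarray).copy()
        self.centroids = self.triangles.mean(axis=1)
        radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_radius = float(radii.max())
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, triangle indices)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = points.shape[0]
        d_cent, _ = self.tree.query(points)
        # any triangle whose centroid is farther than this cannot contain
        # a closer point than the best candidate
        radius = d_cent + 2.0 * self.max_radius + 1e-9
        out_pts = np.empty_like(points)
        out_d = np.empty(n)
        out_tri = np.empty(n, dtype=np.int64)
        groups = self.tree.query_ball_point(points, radius)
        for i, cand in enumerate(groups):
            cand = np.asarray(cand, dtype=np.int64)
            tri = self.triangles[cand]
            q = point_triangle_closest(np.broadcast_to(points[i], (len(cand), 3)), tri)
            d2 = np.einsum("ij,ij->i", q - points[i], q - points[i])
            j = int(np.argmin(d2))
            out_pts[i] = q[j]
            out_d[i] = np.sqrt(d2[j])
            out_tri[i] = cand[j]
        return out_pts, out_d, out_tri


def closest_point_on_mesh(mesh: trimesh.Trimesh, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest point on ``mesh`` for each query point."""
    return SurfaceLocator(mesh).query(points)


def closest_point_brute_force(mesh: trimesh.Trimesh, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs reference oracle: test every triangle for every point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = mesh.triangles.view(np.ndarray)
    m = len(tris)
    out_pts = np.empty_like(points)
    out_d = np.empty(points.shape[0])
    out_tri = np.empty(points.shape[0], dtype=np.int64)
    for i, p in enumerate(points):
        q = point_triangle_closest(np.broadcast_to(p, (m, 3)), tris)
        d2 = np.einsum("ij,ij->i", q - p, q - p)
        j = int(np.argmin(d2))
        out_pts[i], out_d[i], out_tri[i] = q[j], np.sqrt(d2[j]), j
    return out_pts, out_d, out_tri
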