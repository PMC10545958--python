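"""Exact point-to-surface queries and point-in-mesh tests.

Implements closest-point-on-triangle projection (Ericson's region method)
with a KD-tree candidate search, and generalized-winding-number containment,
both pure numpy/scipy. These primitives back the shape-comparison and
meshing stages.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import SurfaceMesh


def closest_point_on_triangle(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Closest points on triangles (a, b, c) to points p, all (N, 3).

    Vectorised Voronoi-region case analysis; exact for degenerate queries on
    vertices/edges.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    # vertex region A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex region B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # vertex region C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceDistance:
    """KD-tree-accelerated exact point-to-surface queries on a triangle mesh.

    A nearest-centroid query gives an upper bound on the surface distance;
    all triangles whose centroid can still beat that bound (centroid within
    bound + max triangle radius) are then tested exactly.
    """

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        v = mesh.vertices
        self.tri = v[mesh.triangles]                      # (T, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.radius = float(
            np.max(np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2))
        )
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest point, distance, triangle id) for each query point."""
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        closest = np.empty((n, 3))
        dist = np.empty(n)
        tri_id = np.empty(n, int)

        _, seed = self.tree.query(points)
        seed_tri = self.tri[seed]
        cp = closest_point_on_triangle(
            points, seed_tri[:, 0], seed_tri[:, 1], seed_tri[:, 2]
        )
        upper = np.linalg.norm(points - cp, axis=1)
        closest[:] = cp
        dist[:] = upper
        tri_id[:] = seed

        cand_lists = self.tree.query_ball_point(points, upper + self.radius + 1e-12)
        for i, cand in enumerate(cand_lists):
            cand = np.asarray(cand, int)
            cand = cand[cand != seed[i]]
            if cand.size == 0:
                continue
            t = self.tri[cand]
            p = np.broadcast_to(points[i], (len(cand), 3))
            cps = closest_point_on_triangle(p.copy(), t[:, 0], t[:, 1], t[:, 2])
            ds = np.linalg.norm(cps - points[i], axis=1)
            j = int(np.argmin(ds))
            if ds[j] < dist[i]:
                dist[i] = ds[j]
                closest[i] = cps[j]
                tri_id[i] = cand[j]
        return closest, dist, tri_id


def closest_point(
    mesh: SurfaceMesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-shot exact closest-point query (builds the index each call)."""
    return SurfaceDistance(mesh).query(points)


def winding_number(mesh: SurfaceMesh, points: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Generalized winding number of each point (1 inside a watertight,
    outward-oriented surface; 0 outside), via the van Oosterom–Strackee
    solid-angle formula summed over triangles."""
    points = np.atleast_2d(np.asarray(points, float))
    tri = mesh.vertices[mesh.triangles]                   # (T, 3, 3)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        a = tri[None, :, 0, :] - p[:, None, :]            # (P, T, 3)
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("ptj,ptj->pt", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ptj,ptj->pt", a, b) * lc
            + np.einsum("ptj,ptj->pt", b, c) * la
            + np.einsum("ptj,ptj->pt", c, a) * lb
        )
        out[s : s + chunk] = np.sum(np.arctan2(num, den), axis=1) / (2.0 * np.pi)
    return out


def contains(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Point-in-mesh test for a watertight, outward-oriented surface."""
    return winding_number(mesh, points) > 0.5


def signed_distance(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Distance to the surface, positive for points OUTSIDE the mesh
    (the bone-growth convention used by the error maps)."""
    points = np.atleast_2d(np.asarray(points, float))
    _, d, _ = SurfaceDistance(mesh).query(points)
    sign = np.where(contains(mesh, points), -1.0, 1.0)
    return sign * d
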