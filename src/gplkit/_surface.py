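"""Exact closest-point-on-surface queries against a triangle mesh.

Two-stage scheme: a cKDTree over triangle centroids proposes candidate
triangles, exact point-to-triangle distances are computed for them, and a
radius bound certifies exactness — the true closest triangle has its
centroid within (best distance so far + largest centroid-to-corner radius)
of the query point, so any point whose candidate ring does not provably
contain that ball is re-queried with the exact radius.  Results are
therefore identical to brute-force minimisation over all triangles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each paired query point.

    points: (n, 3); triangles: (n, 3, 3) — one triangle per point.
    Projects onto the triangle plane; if the projection's barycentric
    coordinates are inside, that is the answer, otherwise the nearest point
    on the three edges is taken.
    """
    p = np.asarray(points, float)
    a = triangles[:, 0]
    ab = triangles[:, 1] - a
    ac = triangles[:, 2] - a
    ap = p - a

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

    closest = a + v[:, None] * ab + w[:, None] * ac

    # fall back to the nearest point on the three boundary segments
    out = ~inside
    if np.any(out):
        tri_o = triangles[out]
        p_o = p[out]
        best_d2 = np.full(out.sum(), np.inf)
        best_pt = np.zeros((out.sum(), 3))
        for i, j in ((0, 1), (1, 2), (2, 0)):
            s0 = tri_o[:, i]
            d = tri_o[:, j] - s0
            t = np.einsum("ij,ij->i", p_o - s0, d)
            dd = np.einsum("ij,ij->i", d, d)
            t = np.clip(np.divide(t, dd, out=np.zeros_like(t), where=dd > 0), 0.0, 1.0)
            cand = s0 + t[:, None] * d
            d2 = np.einsum("ij,ij->i", p_o - cand, p_o - cand)
            better = d2 < best_d2
            best_d2[better] = d2[better]
            best_pt[better] = cand[better]
        closest[out] = best_pt
    return closest


def _subdivide_oversized(triangles: np.ndarray, max_levels: int = 4):
    """Midpoint-split triangles whose circumscribing radius is oversized.

    Returns (sub_triangles, parent_index).  Children tile their parent, so
    the minimum point-to-surface distance over the sub-triangles equals the
    distance over the originals.
    """
    centroids = triangles.mean(axis=1)
    radii = np.linalg.norm(triangles - centroids[:, None, :], axis=2).max(axis=1)
    r_target = 2.0 * float(np.median(radii)) if len(radii) > 1 else np.inf
    sub = triangles
    parent = np.arange(len(triangles))
    for _ in range(max_levels):
        centroids = sub.mean(axis=1)
        radii = np.linalg.norm(sub - centroids[:, None, :], axis=2).max(axis=1)
        big = radii > r_target
        if not big.any():
            break
        t = sub[big]
        a, b, c = t[:, 0], t[:, 1], t[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        children = np.concatenate(
            [
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
                np.stack([ab, bc, ca], axis=1),
            ]
        )
        child_parent = np.tile(parent[big], 4)
        sub = np.concatenate([sub[~big], children])
        parent = np.concatenate([parent[~big], child_parent])
    return np.ascontiguousarray(sub), parent


class SurfaceQuery:
    """Reusable exact closest-point query structure for one mesh."""

    def __init__(self, mesh) -> None:
        self.triangles = np.ascontiguousarray(mesh.triangles, dtype=float)
        # oversized triangles (e.g. end-cap fans) inflate the radius bound
        # and defeat the KD pruning; subdivide them for query purposes only
        # (the children tile the parent exactly, so distances are unchanged)
        sub, parent = _subdivide_oversized(self.triangles)
        self._sub = sub
        self._parent = parent
        self.centroids = sub.mean(axis=1)
        # circumscribing radius per sub-triangle (centroid to farthest corner)
        self.radii = np.linalg.norm(sub - self.centroids[:, None, :], axis=2).max(axis=1)
        self.rmax = float(self.radii.max())
        self.tree = cKDTree(self.centroids)
        n_tri = len(sub)
        self.k1 = min(8, n_tri)
        self.k2 = min(128, n_tri)

    def _query_k(self, p: np.ndarray, k: int):
        dc, idx = self.tree.query(p, k=k, workers=1)
        if k == 1:
            dc, idx = dc[:, None], idx[:, None]
        n = len(p)
        cand_closest = closest_point_on_triangles(
            np.repeat(p, k, axis=0), self._sub[idx.ravel()]
        ).reshape(n, k, 3)
        cand_d = np.linalg.norm(cand_closest - p[:, None, :], axis=2)
        best = np.argmin(cand_d, axis=1)
        rows = np.arange(n)
        return cand_closest[rows, best], cand_d[rows, best], idx[rows, best], dc[:, -1]

    def query_fast(self, points: np.ndarray, warm_tri: np.ndarray | None = None):
        """Nearest-candidate query without the exactness certificate.

        Evaluates the k nearest sub-triangles by centroid plus, when given,
        each point's previous matched (parent) triangle.  The warm-start
        candidate makes the returned distance a guaranteed upper bound on
        the previous match distance, which is what keeps an ICP residual
        history monotone; the k-ring makes misses rare and inconsequential.
        """
        p = np.ascontiguousarray(points, dtype=float)
        if p.ndim == 1:
            p = p[None]
        cp, d, sub_idx, _ = self._query_k(p, self.k1)
        tri = self._parent[sub_idx]
        if warm_tri is not None:
            cc = closest_point_on_triangles(p, self.triangles[warm_tri])
            dd = np.linalg.norm(cc - p, axis=1)
            better = dd < d
            cp[better], d[better], tri[better] = cc[better], dd[better], warm_tri[better]
        return cp, d, tri

    def query(self, points: np.ndarray):
        """Return (closest points, distances, triangle indices); exact."""
        p = np.ascontiguousarray(points, dtype=float)
        if p.ndim == 1:
            p = p[None]
        cp, d, sub_idx, dc_last = self._query_k(p, self.k1)

        # a sub-triangle can beat the current best only if its centroid lies
        # within (best distance + rmax); escalate where the candidate ring
        # does not provably cover that ball
        need = np.flatnonzero(dc_last < d + self.rmax)
        if len(need) and self.k2 > self.k1:
            cp2, d2, si2, dc_last2 = self._query_k(p[need], self.k2)
            better2 = d2 < d[need]
            idx2 = need[better2]
            cp[idx2], d[idx2], sub_idx[idx2] = cp2[better2], d2[better2], si2[better2]
            need = need[dc_last2 < np.minimum(d2, d[need]) + self.rmax]
        for i in need:
            cand = np.asarray(
                self.tree.query_ball_point(p[i], d[i] + self.rmax + 1e-12), dtype=int
            )
            if len(cand) == 0:
                continue
            cc = closest_point_on_triangles(
                np.broadcast_to(p[i], (len(cand), 3)), self._sub[cand]
            )
            dd = np.linalg.norm(cc - p[i], axis=1)
            j = int(np.argmin(dd))
            if dd[j] < d[i]:
                d[i], cp[i], sub_idx[i] = dd[j], cc[j], cand[j]
        return cp, d, self._parent[sub_idx]
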