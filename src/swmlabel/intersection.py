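"""Stage 3: fiber–cortical-mesh intersection.

Each fiber extremity is tested against the mesh along a short search
segment: from one resampled point inside the fiber to a linear extrapolation
two point-spacings beyond the endpoint, along the local fiber direction.
Candidate triangles come from a uniform 3D grid (default 1.5 mm cells): the
cells containing the four search-segment sample points plus their 26
neighbours.  Each candidate triangle is tested with the Möller–Trumbore
ray–triangle solution of

    O + t D = (1 - u - v) V0 + u V1 + v V2,

which yields the ray parameter ``t`` and barycentric coordinates ``(u, v)``
of the exact intersection point.  Among hits inside the search range the one
closest to the fiber endpoint (smallest |t|; ties to the lowest triangle
index) is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LabeledMesh

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Uniform grid
# ---------------------------------------------------------------------------

@dataclass
class SpatialGrid:
    """Uniform grid over the mesh bounding box; cells hold triangle indices.

    Every triangle is registered in every cell its axis-aligned bounding box
    overlaps (conservative), so cell lookups never miss a triangle.
    """

    cell_size: float
    origin: np.ndarray
    cells: dict = field(default_factory=dict)

    def cell_of(self, point: np.ndarray) -> tuple:
        return tuple(np.floor((np.asarray(point) - self.origin) / self.cell_size).astype(int))

    def candidates(self, points: np.ndarray) -> np.ndarray:
        """Union of triangle indices in the cells of ``points`` and their
        26-neighbourhoods."""
        found: set = set()
        seen: set = set()
        for p in np.atleast_2d(points):
            ci, cj, ck = self.cell_of(p)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        key = (ci + di, cj + dj, ck + dk)
                        if key in seen:
                            continue
                        seen.add(key)
                        tris = self.cells.get(key)
                        if tris is not None:
                            found.update(tris)
        return np.array(sorted(found), dtype=int)


def build_grid(mesh: LabeledMesh, cell_size: float = 1.5) -> SpatialGrid:
    """Register each triangle in all cells overlapped by its AABB."""
    if mesh.triangles.shape[0] == 0:
        raise ValueError("cannot build a grid on an empty mesh")
    origin = mesh.vertices.min(axis=0) - cell_size
    grid = SpatialGrid(cell_size=cell_size, origin=origin)
    tri_pts = mesh.vertices[mesh.triangles]              # (M, 3, 3)
    lo = np.floor((tri_pts.min(axis=1) - origin) / cell_size).astype(int)
    hi = np.floor((tri_pts.max(axis=1) - origin) / cell_size).astype(int)
    for t in range(tri_pts.shape[0]):
        for i in range(lo[t, 0], hi[t, 0] + 1):
            for j in range(lo[t, 1], hi[t, 1] + 1):
                for k in range(lo[t, 2], hi[t, 2] + 1):
                    grid.cells.setdefault((i, j, k), []).append(t)
    return grid


# ---------------------------------------------------------------------------
# Search segments at fiber extremities
# ---------------------------------------------------------------------------

def endpoint_rays(fiber: np.ndarray) -> list:
    """Per extremity: (origin at endpoint, outward unit direction, t range,
    sample points).

    The search segment runs from the adjacent resampled point (one point
    inside the fiber, t = -d) to two point-spacings beyond the endpoint
    (t = +2d), where d is the local point spacing.  Sample points are the
    four points at t = -d, 0, d, 2d; their cells (plus neighbours) define
    the candidate triangle set.
    """
    fiber = np.asarray(fiber, dtype=float)
    out = []
    for inner, end in ((1, 0), (-2, -1)):
        vec = fiber[end] - fiber[inner]
        d = np.linalg.norm(vec)
        if d < _EPS:
            out.append(None)
            continue
        direction = vec / d
        samples = np.stack([fiber[end] + t * direction for t in (-d, 0.0, d, 2 * d)])
        out.append((fiber[end].copy(), direction, (-d, 2 * d), samples))
    return out


# ---------------------------------------------------------------------------
# Möller–Trumbore
# ---------------------------------------------------------------------------

def ray_triangle(O, D, V0, V1, V2):
    """Möller–Trumbore ray–triangle intersection.

    Returns ``(t, u, v)`` if the ray ``O + t D`` meets the triangle
    (``u >= 0``, ``v >= 0``, ``u + v <= 1``; ``t`` unbounded — range checks
    are the caller's), else ``None``.  Degenerate triangles warn and miss.
    """
    O, D = np.asarray(O, float), np.asarray(D, float)
    V0, V1, V2 = (np.asarray(v, float) for v in (V0, V1, V2))
    e1, e2 = V1 - V0, V2 - V0
    p = np.cross(D, e2)
    det = e1 @ p
    if abs(det) < _EPS:
        if np.linalg.norm(np.cross(e1, e2)) < _EPS:
            warnings.warn("degenerate triangle in ray_triangle")
        return None
    inv = 1.0 / det
    tvec = O - V0
    u = (tvec @ p) * inv
    if u < 0.0 or u > 1.0:
        return None
    q = np.cross(tvec, e1)
    v = (D @ q) * inv
    if v < 0.0 or u + v > 1.0:
        return None
    t = (e2 @ q) * inv
    return (float(t), float(u), float(v))


def _ray_triangles_vec(O, D, tri_pts):
    """Vectorized Möller–Trumbore over a stack of triangles.

    ``tri_pts``: (m, 3, 3).  Returns (t, u, v, valid) arrays of length m.
    """
    V0, V1, V2 = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    e1, e2 = V1 - V0, V2 - V0
    p = np.cross(D[None, :], e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) >= _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = O[None, :] - V0
    u = np.einsum("ij,ij->i", tvec, p) * inv
    q = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", q, D) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    valid = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
    return t, u, v, valid


# ---------------------------------------------------------------------------
# Per-fiber intersection records
# ---------------------------------------------------------------------------

@dataclass
class IntersectionRecord:
    """Start/end intersection of one fiber with the mesh.

    ``tri_init``/``tri_end`` are triangle indices or -1 for no hit; the
    corresponding point and (u, v) are NaN when absent.
    """

    tri_init: int = -1
    tri_end: int = -1
    point_init: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    point_end: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    uv_init: tuple = (np.nan, np.nan)
    uv_end: tuple = (np.nan, np.nan)

    @property
    def both(self) -> bool:
        return self.tri_init >= 0 and self.tri_end >= 0

    def flipped(self) -> "IntersectionRecord":
        """Record for the same fiber stored in the opposite direction."""
        return IntersectionRecord(self.tri_end, self.tri_init,
                                  self.point_end.copy(), self.point_init.copy(),
                                  self.uv_end, self.uv_init)


def _best_hit(O, D, t_range, cand, tri_pts):
    """Closest-to-endpoint hit among candidate triangles, or None."""
    if cand.size == 0:
        return None
    t, u, v, valid = _ray_triangles_vec(O, D, tri_pts[cand])
    lo, hi = t_range
    tol = 1e-9
    valid &= (t >= lo - tol) & (t <= hi + tol)
    if not valid.any():
        return None
    idx = np.flatnonzero(valid)
    # smallest |t|, ties to lowest triangle index (cand is sorted)
    order = np.lexsort((cand[idx], np.abs(t[idx])))
    best = idx[order[0]]
    return int(cand[best]), float(t[best]), float(u[best]), float(v[best])


def intersect_fiber(fiber: np.ndarray, mesh: LabeledMesh,
                    grid: SpatialGrid | None = None) -> IntersectionRecord:
    """Intersect one resampled fiber's extremities with the mesh.

    With ``grid=None`` all triangles are tested (brute force) — used as the
    reference path in equivalence tests.
    """
    tri_pts = mesh.vertices[mesh.triangles]
    rec = IntersectionRecord()
    rays = endpoint_rays(fiber)
    for which, ray in zip(("init", "end"), rays):
        if ray is None:
            continue
        O, D, t_range, samples = ray
        if grid is None:
            cand = np.arange(mesh.triangles.shape[0])
        else:
            cand = grid.candidates(samples)
        hit = _best_hit(O, D, t_range, cand, tri_pts)
        if hit is None:
            continue
        tri, t, u, v = hit
        point = O + t * D
        if which == "init":
            rec.tri_init, rec.point_init, rec.uv_init = tri, point, (u, v)
        else:
            rec.tri_end, rec.point_end, rec.uv_end = tri, point, (u, v)
    return rec


def intersect_fibers(fibers: np.ndarray, mesh: LabeledMesh,
                     grid: SpatialGrid | None = None) -> list:
    """Intersection records for a stack of resampled fibers."""
    if grid is None:
        grid = build_grid(mesh)
    return [intersect_fiber(f, mesh, grid) for f in fibers]
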