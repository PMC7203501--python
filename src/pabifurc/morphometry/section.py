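"""Plane/mesh cross-sections and their scalar metrics.

A cross-section is the closed polygon where a plane cuts the vessel
wall.  Areas use the shoelace rule on the ordered loop, the perimeter is
the edge-length sum, the hydraulic diameter is ``4 * area / perimeter``
and the maximal diameter is the max Feret (largest vertex-pair
distance).  Metric operations report the scaled clinical units; the
polygon itself stays in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

from pabifurc import units

__all__ = [
    "SectionPolygon",
    "SectionError",
    "MultiLoopSectionError",
    "NoIntersectionError",
    "cross_section",
    "cross_section_loops",
    "csa",
    "perimeter",
    "hydraulic_diameter",
    "maximal_diameter",
]


class SectionError(ValueError):
    pass


class NoIntersectionError(SectionError):
    """The plane does not cut the surface in any closed loop."""


class MultiLoopSectionError(SectionError):
    """The plane cuts the surface in several closed loops.

    Used as a *signal* by plane placement: it means the plane crosses
    the carina (or another multi-lumen region).
    """

    def __init__(self, loops):
        self.loops = loops
        super().__init__(f"plane intersects surface in {len(loops)} closed loops")


def _plane_basis(normal: np.ndarray):
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return normal, u, v


@dataclass
class SectionPolygon:
    """Closed planar loop in mm: plane frame plus ordered 2-D vertices."""

    origin: np.ndarray
    normal: np.ndarray
    loop2d: np.ndarray  # (n, 2), counter-clockwise
    basis_u: np.ndarray
    basis_v: np.ndarray

    def __post_init__(self):
        if len(self.loop2d) < 3:
            raise SectionError("section polygon needs at least 3 vertices")

    @property
    def loop3d(self) -> np.ndarray:
        return (
            self.origin
            + self.loop2d[:, :1] * self.basis_u
            + self.loop2d[:, 1:] * self.basis_v
        )

    def _require_simple(self) -> None:
        if not ShapelyPolygon(self.loop2d).is_valid:
            raise SectionError("section loop is self-intersecting")

    # metrics in base mm units -------------------------------------------

    def area_mm2(self) -> float:
        self._require_simple()
        x, y = self.loop2d[:, 0], self.loop2d[:, 1]
        x2, y2 = np.roll(x, -1), np.roll(y, -1)
        return float(abs(0.5 * np.sum(x * y2 - x2 * y)))

    def perimeter_mm(self) -> float:
        self._require_simple()
        d = np.roll(self.loop2d, -1, axis=0) - self.loop2d
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def maximal_diameter_mm(self) -> float:
        pts = self.loop2d
        if len(pts) > 16:
            pts = pts[ConvexHull(pts).vertices]
        diff = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((diff ** 2).sum(-1)).max())

    def centroid_mm(self) -> np.ndarray:
        """Area centroid, mapped back to 3-D."""
        x, y = self.loop2d[:, 0], self.loop2d[:, 1]
        x2, y2 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y2 - x2 * y
        signed = 0.5 * np.sum(cross)
        cx = np.sum((x + x2) * cross) / (6.0 * signed)
        cy = np.sum((y + y2) * cross) / (6.0 * signed)
        return self.origin + cx * self.basis_u + cy * self.basis_v


# ------------------------------------------------------------- operations


def csa(polygon: SectionPolygon) -> float:
    """Cross-sectional area in 100 mm^2."""
    return units.area_to_reported(polygon.area_mm2())


def perimeter(polygon: SectionPolygon) -> float:
    """Loop perimeter in 10 mm."""
    return units.length_to_reported(polygon.perimeter_mm())


def hydraulic_diameter(csa_value: float, perimeter_value: float) -> float:
    """``4 * CSA / perimeter`` for unit-consistent positive inputs.

    Works on any consistent unit pair; with the reported scales
    (100 mm^2, 10 mm) the result is in 10 mm units.
    """
    if csa_value <= 0 or perimeter_value <= 0:
        raise ValueError("csa and perimeter must be positive")
    return 4.0 * csa_value / perimeter_value


def maximal_diameter(polygon: SectionPolygon) -> float:
    """Max Feret diameter in 10 mm."""
    return units.length_to_reported(polygon.maximal_diameter_mm())


# ------------------------------------------------------------ mesh slicing


def cross_section_loops(surface, origin, normal):
    """All closed intersection loops of a plane with the surface.

    Open chains (the plane crossing a vessel opening) are discarded.
    Returns a list of :class:`SectionPolygon`, each oriented CCW about
    the plane normal.
    """
    origin = np.asarray(origin, dtype=float)
    n, u, v = _plane_basis(normal)
    verts = surface.vertices
    d = (verts - origin) @ n
    d = np.where(d == 0.0, 1e-12, d)

    pos = d > 0
    faces = surface.faces
    fpos = pos[faces]
    crossing = (fpos.any(axis=1)) & (~fpos.all(axis=1))
    if not crossing.any():
        raise NoIntersectionError("plane does not intersect the surface")

    def edge_key(i, j):
        return (i, j) if i < j else (j, i)

    points: dict = {}

    def cut(i, j):
        key = edge_key(i, j)
        if key not in points:
            t = d[i] / (d[i] - d[j])
            points[key] = verts[i] + t * (verts[j] - verts[i])
        return key

    adjacency: dict = {}
    for tri in faces[crossing]:
        keys = []
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            if pos[a] != pos[b]:
                keys.append(cut(a, b))
        if len(keys) != 2:
            continue
        k0, k1 = keys
        adjacency.setdefault(k0, []).append(k1)
        adjacency.setdefault(k1, []).append(k0)

    loops = []
    visited: set = set()
    for start in adjacency:
        if start in visited or len(adjacency[start]) != 2:
            continue
        chain = [start]
        visited.add(start)
        prev, cur = start, adjacency[start][0]
        closed = False
        while True:
            if cur == start:
                closed = True
                break
            if cur in visited or len(adjacency.get(cur, ())) != 2:
                break  # open chain: plane crosses a boundary
            chain.append(cur)
            visited.add(cur)
            nbrs = adjacency[cur]
            nxt = nbrs[0] if nbrs[1] == prev else nbrs[1]
            prev, cur = cur, nxt
        if closed and len(chain) >= 3:
            pts3 = np.array([points[k] for k in chain])
            rel = pts3 - origin
            loop2d = np.column_stack([rel @ u, rel @ v])
            x, y = loop2d[:, 0], loop2d[:, 1]
            if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
                loop2d = loop2d[::-1]
            loops.append(SectionPolygon(origin, n, loop2d, u, v))
    if not loops:
        raise NoIntersectionError("plane cuts only open boundary chains")
    return loops


def cross_section(surface, origin, normal) -> SectionPolygon:
    """The single closed loop containing the origin's in-plane projection.

    Raises :class:`MultiLoopSectionError` when the plane yields several
    closed loops (carina signal) and :class:`NoIntersectionError` when
    it yields none.
    """
    loops = cross_section_loops(surface, origin, normal)
    if len(loops) > 1:
        raise MultiLoopSectionError(loops)
    loop = loops[0]
    # membership check: the origin projects to (0, 0) in plane coordinates
    if not ShapelyPolygon(loop.loop2d).contains(ShapelyPoint(0.0, 0.0)):
        raise SectionError("section loop does not contain the plane origin")
    return loop
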