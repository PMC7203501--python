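"""Centerline recovery by iterative centroid marching.

Starting from a vessel opening, the tracker repeatedly slices the mesh
perpendicular to its running tangent, re-centres on the section's area
centroid and steps forward.  Marching stops at a vessel end (no further
intersection) or at the junction (multi-loop section or a sharp change
of section area).  This is deliberately simple — deterministic and
adequate for tubular, single-bifurcation topologies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from pabifurc.mesh import MeshError, VesselSurface
from pabifurc.morphometry.section import (
    MultiLoopSectionError,
    NoIntersectionError,
    SectionError,
    cross_section_loops,
)

__all__ = ["Centerline", "MarchResult", "march_centerline", "extract_centerline"]

#: relative section-area jump between consecutive steps that flags the junction
_AREA_JUMP = 0.18


@dataclass
class MarchResult:
    points: np.ndarray          # (n, 3) section centroids, in marching order
    areas: np.ndarray           # (n,) section areas, mm^2
    status: str                 # "end" | "junction"
    last_tangent: np.ndarray

    @property
    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Centerline:
    """Branch-labelled centreline polylines (mm).

    ``branches`` maps branch tags (``MPA``, ``RPA``, ``LPA``) to ordered
    point arrays; the trunk runs inlet -> bifurcation, branch paths run
    bifurcation -> outlet.  ``bifurcation_point`` is the last trunk
    point.
    """

    branches: Dict[str, np.ndarray]
    areas: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def bifurcation_point(self) -> np.ndarray:
        return self.branches["MPA"][-1]

    def arc_lengths(self, tag: str) -> np.ndarray:
        pts = self.branches[tag]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _loop_plane_frame(surface: VesselSurface, loop) -> tuple:
    """Centroid and best-fit unit normal of a boundary loop."""
    pts = surface.vertices[loop]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


def _single_section(surface, origin, normal):
    loops = cross_section_loops(surface, origin, normal)
    if len(loops) > 1:
        raise MultiLoopSectionError(loops)
    return loops[0]


def march_centerline(
    surface: VesselSurface,
    start: np.ndarray,
    direction: np.ndarray,
    step: float = 1.0,
    max_steps: int = 1000,
) -> MarchResult:
    """Track one vessel path from ``start`` along ``direction``."""
    t = np.asarray(direction, dtype=float)
    t = t / np.linalg.norm(t)
    p = np.asarray(start, dtype=float)

    sec = _single_section(surface, p, t)
    c = sec.centroid_mm()
    points = [c]
    areas = [sec.area_mm2()]
    status = "end"

    for _ in range(max_steps):
        probe = points[-1] + step * t
        try:
            sec = _single_section(surface, probe, t)
        except (MultiLoopSectionError, NoIntersectionError) as exc:
            status = "junction" if isinstance(exc, MultiLoopSectionError) else "end"
            break
        c = sec.centroid_mm()
        # one re-centring pass with the updated tangent
        t_new = c - points[-1]
        norm = np.linalg.norm(t_new)
        if norm < 1e-9:
            status = "end"
            break
        t_new = t_new / norm
        try:
            sec = _single_section(surface, c, t_new)
            c = sec.centroid_mm()
        except (MultiLoopSectionError, NoIntersectionError, SectionError):
            pass  # keep the un-refined point
        area = sec.area_mm2()
        if abs(area - areas[-1]) / areas[-1] > _AREA_JUMP:
            status = "junction"
            break
        t = t_new
        points.append(c)
        areas.append(area)

    return MarchResult(
        points=np.array(points),
        areas=np.array(areas),
        status=status,
        last_tangent=t,
    )


def extract_centerline(
    surface: VesselSurface,
    inlet: Optional[int] = None,
    step: float = 1.0,
) -> Centerline:
    """Trunk and branch centrelines of a three-opening vessel surface.

    ``inlet`` selects the trunk opening (boundary-loop index); defaults
    to the surface's ``MPA`` opening label, falling back to the largest
    opening.  Branch tags come from opening labels when present,
    otherwise the branch ending at larger x is called ``RPA``.
    """
    if not surface.is_manifold():
        raise MeshError("surface is not manifold")
    loops = surface.boundary_loops()
    if len(loops) != 3:
        raise MeshError(f"expected exactly 3 vessel openings, found {len(loops)}")

    if inlet is None:
        inlet = surface.opening_labels.get("MPA")
    if inlet is None:
        sizes = []
        for loop in loops:
            pts = surface.vertices[loop]
            c = pts.mean(axis=0)
            sizes.append(np.linalg.norm(pts - c, axis=1).mean())
        inlet = int(np.argmax(sizes))

    interior = surface.vertices.mean(axis=0)

    def inward(centroid, normal):
        return normal if (interior - centroid) @ normal > 0 else -normal

    c0, n0 = _loop_plane_frame(surface, loops[inlet])
    trunk = march_centerline(surface, c0 + 1e-3 * inward(c0, n0), inward(c0, n0), step)

    branch_results = {}
    for idx in range(3):
        if idx == inlet:
            continue
        cb, nb = _loop_plane_frame(surface, loops[idx])
        branch_results[idx] = march_centerline(
            surface, cb + 1e-3 * inward(cb, nb), inward(cb, nb), step
        )

    label_for = {}
    inv = {v: k for k, v in surface.opening_labels.items()}
    if set(inv) >= set(branch_results) and all(
        inv.get(i) in ("RPA", "LPA") for i in branch_results
    ):
        label_for = {i: inv[i] for i in branch_results}
    else:
        items = sorted(
            branch_results.items(), key=lambda kv: kv[1].points[0][0], reverse=True
        )
        label_for = {items[0][0]: "RPA", items[1][0]: "LPA"}

    branches = {"MPA": trunk.points}
    areas = {"MPA": trunk.areas}
    for idx, res in branch_results.items():
        tag = label_for[idx]
        branches[tag] = res.points[::-1]  # run bifurcation -> outlet
        areas[tag] = res.areas[::-1]
    return Centerline(branches=branches, areas=areas)
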