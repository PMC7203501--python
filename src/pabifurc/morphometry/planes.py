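"""Placement of the four measurement planes.

Plane normals are local centreline tangents.  The trunk inlet plane
sits at the proximal end of the trunk path.  The trunk outlet and the
two branch inlet planes are found by carina detection: the station
nearest the junction whose cross-section is still a single simple loop
with a locally stable area (relative change below 4 % per mm), refined
by bisection to 0.1 mm arc length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pabifurc import units
from pabifurc.morphometry.centerline import Centerline
from pabifurc.morphometry.section import (
    MultiLoopSectionError,
    NoIntersectionError,
    SectionError,
    SectionPolygon,
    cross_section_loops,
)

__all__ = [
    "PlaneMetrics",
    "MeasurementPlane",
    "NoCarinaError",
    "select_measurement_planes",
]

PLANE_IDS = ("MPA_inlet", "MPA_outlet", "RPA_inlet", "LPA_inlet")

#: carina-detection thresholds, shared with the synthetic ground truth
GROWTH_MAX_PER_MM = 0.04
PROBE_MM = 1.0
BISECT_TOL_MM = 0.1


class NoCarinaError(ValueError):
    """No junction (or no clean station) found along a path."""


@dataclass
class PlaneMetrics:
    """Per-plane scalar metrics in reported units."""

    plane_id: str
    csa: float                  # 100 mm^2
    perimeter: float            # 10 mm
    hydraulic_diameter: float   # 10 mm
    maximal_diameter: float     # 10 mm

    @classmethod
    def from_polygon(cls, plane_id: str, polygon: SectionPolygon) -> "PlaneMetrics":
        area = polygon.area_mm2()
        perim = polygon.perimeter_mm()
        return cls(
            plane_id=plane_id,
            csa=units.area_to_reported(area),
            perimeter=units.length_to_reported(perim),
            hydraulic_diameter=units.length_to_reported(4.0 * area / perim),
            maximal_diameter=units.length_to_reported(polygon.maximal_diameter_mm()),
        )


@dataclass
class MeasurementPlane:
    plane_id: str
    origin: np.ndarray          # section centroid (mm)
    normal: np.ndarray          # unit tangent
    station_mm: float           # arc length along its path
    polygon: SectionPolygon
    metrics: PlaneMetrics


class _Path:
    """Arc-length parameterised polyline with linear extrapolation."""

    def __init__(self, points: np.ndarray):
        self.points = np.asarray(points, dtype=float)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.s = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self.s[-1])

    def point_at(self, s: float) -> np.ndarray:
        if s <= 0:
            t = self.tangent_at(0.0)
            return self.points[0] + s * t
        if s >= self.length:
            t = self.tangent_at(self.length)
            return self.points[-1] + (s - self.length) * t
        i = int(np.searchsorted(self.s, s) - 1)
        i = max(0, min(i, len(self.s) - 2))
        f = (s - self.s[i]) / (self.s[i + 1] - self.s[i])
        return self.points[i] + f * (self.points[i + 1] - self.points[i])

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.s, s) - 1, 0, len(self.s) - 2))
        t = self.points[i + 1] - self.points[i]
        return t / np.linalg.norm(t)


def _single_loop(surface, origin, normal):
    loops = cross_section_loops(surface, origin, normal)
    if len(loops) > 1:
        raise MultiLoopSectionError(loops)
    return loops[0]


def _section_area(surface, path: _Path, s: float) -> float:
    sec = _single_loop(surface, path.point_at(s), path.tangent_at(s))
    return sec.area_mm2()


def _is_clean(surface, path: _Path, s: float, toward: float) -> bool:
    try:
        a0 = _section_area(surface, path, s)
        a1 = _section_area(surface, path, s + toward * PROBE_MM)
    except (MultiLoopSectionError, NoIntersectionError, SectionError):
        return False
    return abs(a1 - a0) / (PROBE_MM * a0) <= GROWTH_MAX_PER_MM


def _refine_station(surface, path: _Path, toward: float, branch_name: str,
                    scan_from: float, scan_to: float) -> float:
    """Clean station nearest the carina, to BISECT_TOL_MM."""
    grid = np.arange(scan_from, scan_to, 0.5 * np.sign(scan_to - scan_from))
    s_ok = s_bad = None
    for s in grid:
        if _is_clean(surface, path, s, toward):
            s_ok = s
        else:
            s_bad = s
            break
    if s_ok is None:
        raise NoCarinaError(
            f"no clean single-loop station found along {branch_name}"
        )
    if s_bad is None:
        raise NoCarinaError(f"no carina found along {branch_name}")
    while abs(s_bad - s_ok) > BISECT_TOL_MM:
        mid = 0.5 * (s_ok + s_bad)
        if _is_clean(surface, path, mid, toward):
            s_ok = mid
        else:
            s_bad = mid
    return float(s_ok)


def _plane_at(surface, path: _Path, s: float, plane_id: str) -> MeasurementPlane:
    normal = path.tangent_at(s)
    polygon = _single_loop(surface, path.point_at(s), normal)
    return MeasurementPlane(
        plane_id=plane_id,
        origin=polygon.centroid_mm(),
        normal=normal,
        station_mm=float(s),
        polygon=polygon,
        metrics=PlaneMetrics.from_polygon(plane_id, polygon),
    )


def select_measurement_planes(surface, centerline: Centerline) -> dict:
    """The four measurement planes keyed by :data:`PLANE_IDS`.

    Raises :class:`NoCarinaError` (naming the branch) when a path has no
    junction or no clean station.
    """
    if "RPA" not in centerline.branches or "LPA" not in centerline.branches:
        raise NoCarinaError("no carina found: centerline has no branch paths")

    trunk = _Path(centerline.branches["MPA"])
    planes = {"MPA_inlet": _plane_at(surface, trunk, 0.0, "MPA_inlet")}

    # trunk outlet: scan distally past the marching stop (straight-line
    # extrapolation beyond the path end is fine that close to the carina)
    s_out = _refine_station(
        surface, trunk, toward=+1.0, branch_name="MPA",
        scan_from=max(0.0, trunk.length - 15.0), scan_to=trunk.length + 8.0,
    )
    planes["MPA_outlet"] = _plane_at(surface, trunk, s_out, "MPA_outlet")

    for tag in ("RPA", "LPA"):
        path = _Path(centerline.branches[tag])  # runs bifurcation -> outlet
        s_in = _refine_station(
            surface, path, toward=-1.0, branch_name=tag,
            scan_from=max(1.0, path.length - 1.0), scan_to=-8.0,
        )
        planes[f"{tag}_inlet"] = _plane_at(surface, path, s_in, f"{tag}_inlet")
    return planes
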