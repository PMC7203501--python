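"""Parametric bifurcation meshes with analytic ground truth.

The generator models a trunk vessel (optionally elliptical and tapered)
that splits into two circular daughter branches.  The solid is defined
implicitly as a smooth union of three capped tubes; the surface mesh is
extracted by marching cubes and the three vessel ends are opened by
clipping, so the result is a manifold mesh with exactly three boundary
loops.

Every ground-truth quantity is computed from the *implicit* geometry
(closed forms where available, 2-D contouring and 3-D voxel counting of
the signed field otherwise), never from the emitted mesh — downstream
mesh measurements can therefore be validated against an independent
route.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import special
from skimage import measure

from pabifurc.mesh import VesselSurface, clip_halfspace

__all__ = [
    "BifurcationSpec",
    "GroundTruth",
    "GeometryConflictError",
    "generate_bifurcation_mesh",
    "cylinder_mesh",
    "arc_tube_mesh",
    "ellipse_perimeter",
    "voxel_volume",
]


class GeometryConflictError(ValueError):
    """Requested tube arrangement is geometrically inconsistent."""


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral."""
    a, b = max(a, b), min(a, b)
    m = 1.0 - (b / a) ** 2
    return float(4.0 * a * special.ellipe(m))


# --------------------------------------------------------------------- spec


@dataclass(frozen=True)
class BifurcationSpec:
    """Parameters of a trunk -> (right, left) branch bifurcation.

    Lengths and radii in mm, angles in degrees from the trunk axis.
    ``ellipticity_trunk`` is the minor/major semi-axis ratio of the trunk
    cross-section (major axis along x).  ``mesh_resolution`` is the
    number of segments resolved around the thinnest ring; it fixes the
    marching-cubes voxel pitch.
    """

    trunk_length: float = 45.0
    trunk_radius_inlet: float = 14.0
    trunk_radius_outlet: float = 15.0
    ellipticity_trunk: float = 0.9
    branch_radii: Tuple[float, float] = (9.5, 9.5)
    branch_lengths: Tuple[float, float] = (34.0, 34.0)
    branch_angles: Tuple[float, float] = (45.0, 45.0)
    carina_offset: float = 0.0
    fillet_radius: float = 2.5
    mesh_resolution: int = 64
    seed: int = 0

    def validate(self) -> None:
        pos = [
            self.trunk_length,
            self.trunk_radius_inlet,
            self.trunk_radius_outlet,
            *self.branch_radii,
            *self.branch_lengths,
        ]
        if any(x <= 0 for x in pos):
            raise ValueError("all lengths and radii must be > 0")
        if not (0.0 < self.ellipticity_trunk <= 1.0):
            raise ValueError("ellipticity_trunk must lie in (0, 1]")
        if any(not (0.0 < a < 90.0) for a in self.branch_angles):
            raise ValueError("branch_angles must lie in (0, 90) degrees")
        if self.mesh_resolution < 16:
            raise ValueError("mesh_resolution must be >= 16 segments per ring")
        if self.fillet_radius < 0:
            raise ValueError("fillet_radius must be >= 0")
        # branch tubes must separate before their far ends
        er, el = self.branch_ends
        if np.linalg.norm(er - el) < sum(self.branch_radii) + 1.0:
            raise GeometryConflictError(
                "branch tubes never separate: angles/lengths/radii conflict"
            )

    # geometry anchors -----------------------------------------------------

    @property
    def bifurcation_origin(self) -> np.ndarray:
        return np.array([self.carina_offset, 0.0, self.trunk_length])

    @property
    def branch_directions(self) -> Tuple[np.ndarray, np.ndarray]:
        ar, al = np.radians(self.branch_angles)
        right = np.array([np.sin(ar), 0.0, np.cos(ar)])
        left = np.array([-np.sin(al), 0.0, np.cos(al)])
        return right, left

    @property
    def branch_ends(self) -> Tuple[np.ndarray, np.ndarray]:
        b = self.bifurcation_origin
        ur, ul = self.branch_directions
        return b + self.branch_lengths[0] * ur, b + self.branch_lengths[1] * ul

    def trunk_radius_at(self, z) -> np.ndarray:
        t = np.clip(np.asarray(z, dtype=float) / self.trunk_length, 0.0, 1.0)
        return self.trunk_radius_inlet + t * (self.trunk_radius_outlet - self.trunk_radius_inlet)

    @property
    def voxel_pitch(self) -> float:
        rmin = min(
            min(self.branch_radii),
            self.ellipticity_trunk * min(self.trunk_radius_inlet, self.trunk_radius_outlet),
        )
        return 2.0 * np.pi * rmin / self.mesh_resolution

    def to_dict(self) -> dict:
        return {
            "trunk_length": self.trunk_length,
            "trunk_radius_inlet": self.trunk_radius_inlet,
            "trunk_radius_outlet": self.trunk_radius_outlet,
            "ellipticity_trunk": self.ellipticity_trunk,
            "branch_radii": list(self.branch_radii),
            "branch_lengths": list(self.branch_lengths),
            "branch_angles": list(self.branch_angles),
            "carina_offset": self.carina_offset,
            "fillet_radius": self.fillet_radius,
            "mesh_resolution": self.mesh_resolution,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BifurcationSpec":
        d = dict(d)
        for key in ("branch_radii", "branch_lengths", "branch_angles"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ----------------------------------------------------------- implicit field


class ImplicitBifurcation:
    """Signed scalar field; negative inside the vessel lumen."""

    def __init__(self, spec: BifurcationSpec):
        self.spec = spec
        self.origin = spec.bifurcation_origin
        self.dirs = spec.branch_directions

    def _trunk(self, pts: np.ndarray) -> np.ndarray:
        s = self.spec
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        a = s.trunk_radius_at(z)
        b = s.ellipticity_trunk * a
        rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        radial = (rho - 1.0) * b  # exact zero level, approximate distance
        return np.maximum(radial, np.maximum(-z, z - s.trunk_length))

    def _branch(self, pts: np.ndarray, which: int) -> np.ndarray:
        s = self.spec
        u = self.dirs[which]
        r = s.branch_radii[which]
        length = s.branch_lengths[which]
        rel = pts - self.origin
        d = rel @ u
        radial = np.linalg.norm(rel - d[:, None] * u[None, :], axis=1) - r
        return np.maximum(radial, np.maximum(-d, d - length))

    @staticmethod
    def _smooth_min(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
        if k <= 0:
            return np.minimum(a, b)
        h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
        return b + (a - b) * h - k * h * (1.0 - h)

    def __call__(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        k = self.spec.fillet_radius
        f = self._smooth_min(self._trunk(pts), self._branch(pts, 0), k)
        return self._smooth_min(f, self._branch(pts, 1), k)

    def bounding_box(self, pad: float = 3.0):
        s = self.spec
        rmax = max(s.trunk_radius_inlet, s.trunk_radius_outlet)
        er, el = s.branch_ends
        rr, rl = s.branch_radii
        lo = np.array(
            [
                min(-rmax + min(0.0, s.carina_offset), el[0] - rl) - pad,
                -max(rmax * s.ellipticity_trunk, rr, rl) - pad,
                -pad,
            ]
        )
        hi = np.array(
            [
                max(rmax + max(0.0, s.carina_offset), er[0] + rr) + pad,
                max(rmax * s.ellipticity_trunk, rr, rl) + pad,
                max(er[2] + rr, el[2] + rl) + pad,
            ]
        )
        return lo, hi


# ------------------------------------------------------------ ground truth


@dataclass
class GroundTruth:
    """Analytic / implicit-geometry reference values, all in base mm units."""

    centerlines: Dict[str, np.ndarray]
    planes: Dict[str, dict]
    bifurcation: Dict[str, float]
    spec: BifurcationSpec = None

    def to_json(self, path) -> None:
        payload = {
            "centerlines": {k: np.asarray(v).tolist() for k, v in self.centerlines.items()},
            "planes": {
                k: {kk: (np.asarray(vv).tolist() if isinstance(vv, np.ndarray) else vv)
                    for kk, vv in d.items()}
                for k, d in self.planes.items()
            },
            "bifurcation": self.bifurcation,
            "spec": self.spec.to_dict() if self.spec else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        planes = {
            k: {kk: (np.array(vv) if kk in ("origin", "normal") else vv)
                for kk, vv in d.items()}
            for k, d in payload["planes"].items()
        }
        return cls(
            centerlines={k: np.array(v) for k, v in payload["centerlines"].items()},
            planes=planes,
            bifurcation=payload["bifurcation"],
            spec=BifurcationSpec.from_dict(payload["spec"]) if payload.get("spec") else None,
        )


def _plane_basis(normal: np.ndarray):
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _implicit_slice(field, origin, normal, half_extent: float, res: float):
    """Sample the field on a plane; returns (grid, u, v, lo)."""
    u, v = _plane_basis(np.asarray(normal, dtype=float))
    n = int(np.ceil(2 * half_extent / res)) + 1
    coords = np.linspace(-half_extent, half_extent, n)
    uu, vv = np.meshgrid(coords, coords, indexing="ij")
    pts = origin + uu[..., None] * u + vv[..., None] * v
    vals = field(pts.reshape(-1, 3)).reshape(uu.shape)
    return vals, u, v, coords

def _slice_loop_count(field, origin, normal, half_extent, res=0.4) -> int:
    vals, *_ = _implicit_slice(field, origin, normal, half_extent, res)
    return int(measure.label(vals < 0, connectivity=1).max())


def _slice_polygon(field, origin, normal, half_extent, res=0.15):
    """Contour of the lumen section containing the plane origin (2-D mm)."""
    vals, u, v, coords = _implicit_slice(field, origin, normal, half_extent, res)
    contours = measure.find_contours(vals, 0.0)
    if not contours:
        raise ValueError("plane does not intersect the lumen")
    step = coords[1] - coords[0]
    best = None
    for c in contours:
        poly = np.column_stack(
            [coords[0] + c[:, 0] * step, coords[0] + c[:, 1] * step]
        )
        # closed contour containing the origin (0, 0)
        if np.linalg.norm(poly[0] - poly[-1]) > 2 * step:
            continue
        x, y = poly[:, 0], poly[:, 1]
        inside = _winding_contains(poly, 0.0, 0.0)
        if inside:
            best = poly
            break
    if best is None:
        # fall back to the largest closed contour
        best = max(contours, key=len)
        best = np.column_stack(
            [coords[0] + best[:, 0] * step, coords[0] + best[:, 1] * step]
        )
    return best, u, v


def _winding_contains(poly: np.ndarray, px: float, py: float) -> bool:
    x = poly[:, 0] - px
    y = poly[:, 1] - py
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)
    ang = np.arctan2(x * y2 - y * x2, x * x2 + y * y2)
    return abs(ang.sum()) > np.pi


def _polygon_metrics(poly: np.ndarray) -> dict:
    x, y = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    signed = 0.5 * np.sum(cross)
    area = abs(signed)
    perim = float(np.sum(np.hypot(x2 - x, y2 - y)))
    cx = float(np.sum((x + x2) * cross) / (6.0 * signed))
    cy = float(np.sum((y + y2) * cross) / (6.0 * signed))
    # max Feret diameter on the convex hull
    from scipy.spatial import ConvexHull

    hull = poly[ConvexHull(poly).vertices]
    diff = hull[:, None, :] - hull[None, :, :]
    dmax = float(np.sqrt((diff ** 2).sum(-1)).max())
    return {
        "csa_mm2": float(area),
        "perimeter_mm": perim,
        "hydraulic_diameter_mm": float(4.0 * area / perim),
        "maximal_diameter_mm": dmax,
        "centroid_2d": (float(cx), float(cy)),
    }


def voxel_volume(field, lo, hi, pitch: float, halfspaces=()) -> float:
    """Volume of {field < 0} intersected with half-spaces, by voxel counting.

    ``halfspaces`` is an iterable of (origin, normal) pairs keeping the
    side with ``dot(x - origin, normal) <= 0``.
    """
    axes = [np.arange(lo[i] + pitch / 2, hi[i], pitch) for i in range(3)]
    total = 0.0
    # chunk along z to bound memory
    xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
    base = np.column_stack([xx.ravel(), yy.ravel()])
    for z in axes[2]:
        pts = np.column_stack([base, np.full(len(base), z)])
        inside = field(pts) < 0
        for origin, normal in halfspaces:
            inside &= (pts - np.asarray(origin)) @ np.asarray(normal) <= 0
        total += inside.sum()
    return float(total) * pitch ** 3


# ------------------------------------------------- station / plane finding


#: maximum tolerated relative section-area growth toward the carina
#: (fraction per mm) before a station counts as inside the junction
PLACEMENT_GROWTH_MAX = 0.04
#: probe distance (mm) for the growth-rate estimate
PLACEMENT_PROBE_MM = 1.0


def _slice_area(field, origin, normal, half_extent, res=0.3) -> float:
    poly, _, _ = _slice_polygon(field, origin, normal, half_extent, res=res)
    return _polygon_metrics(poly)["csa_mm2"]


def _find_clean_station(field, anchor, direction, smin, smax, half_extent,
                        toward_carina: float, res=0.3, tol=0.05):
    """Extreme station whose section is still a clean single vessel lumen.

    A station is *clean* when its section is one simple loop and the
    relative area change toward the carina stays below
    :data:`PLACEMENT_GROWTH_MAX` in magnitude — sections deform sharply
    (and eventually split) as the plane enters the junction.  ``toward_carina`` is +1
    when increasing ``s`` approaches the carina (trunk) and -1 when
    decreasing ``s`` does (branches); the clean station found is the one
    nearest the carina.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    h = PLACEMENT_PROBE_MM

    def clean(s) -> bool:
        origin = anchor + s * direction
        if _slice_loop_count(field, origin, direction, half_extent, res=0.35) != 1:
            return False
        a0 = _slice_area(field, origin, direction, half_extent, res=res)
        a1 = _slice_area(
            field, anchor + (s + toward_carina * h) * direction, direction,
            half_extent, res=res)
        return abs(a1 - a0) / (h * a0) <= PLACEMENT_GROWTH_MAX

    if toward_carina > 0:
        s_grid = np.arange(smin, smax, 1.0)
    else:
        s_grid = np.arange(smax, smin, -1.0)
    s_ok = s_bad = None
    for s in s_grid:
        if clean(s):
            s_ok = s
        else:
            s_bad = s
            break
    if s_ok is None or s_bad is None:
        raise ValueError("no carina transition found in range")
    while abs(s_bad - s_ok) > tol:
        mid = 0.5 * (s_ok + s_bad)
        if clean(mid):
            s_ok = mid
        else:
            s_bad = mid
    return s_ok


def _plane_record(field, origin, normal, station, half_extent) -> dict:
    poly, u, v = _slice_polygon(field, origin, normal, half_extent)
    metrics = _polygon_metrics(poly)
    cx, cy = metrics.pop("centroid_2d")
    center = np.asarray(origin) + cx * u + cy * v
    rec = {
        "station_mm": float(station),
        "origin": np.asarray(origin, dtype=float),
        "normal": np.asarray(normal, dtype=float),
        "center": center,
    }
    rec.update(metrics)
    return rec


# ----------------------------------------------------------- mesh emission


def _marching_cubes_mesh(field, lo, hi, pitch: float) -> VesselSurface:
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([g.ravel() for g in grid])
    vol = field(pts).reshape(grid[0].shape)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    surf = VesselSurface(verts, faces.astype(np.int64))
    if surf.volume() < 0:  # canonicalise to outward-facing triangles
        surf = VesselSurface(surf.vertices, surf.faces[:, ::-1].copy())
    return surf


def generate_bifurcation_mesh(spec: BifurcationSpec):
    """Build the surface mesh and its ground truth.

    Returns
    -------
    (VesselSurface, GroundTruth)
        The mesh is manifold and open exactly at the three vessel ends
        (trunk inlet, right branch end, left branch end).  Ground-truth
        values come from the implicit geometry, independent of the mesh.
    """
    spec.validate()
    field = ImplicitBifurcation(spec)
    pitch = spec.voxel_pitch
    lo, hi = field.bounding_box(pad=max(3.0, 2 * pitch))
    surface = _marching_cubes_mesh(field, lo, hi, pitch)

    # open the three ends by trimming one voxel off each cap
    delta = 1.3 * pitch
    b = spec.bifurcation_origin
    ur, ul = spec.branch_directions
    er, el = spec.branch_ends
    surface = clip_halfspace(surface, np.array([0, 0, delta]), np.array([0, 0, -1.0]))
    surface = clip_halfspace(surface, er - delta * ur, ur)
    surface = clip_halfspace(surface, el - delta * ul, ul)
    surface = surface.compact()
    surface.opening_labels = _label_openings(surface, spec, delta)

    gt = _ground_truth(spec, field, delta)
    return surface, gt


def _label_openings(surface: VesselSurface, spec: BifurcationSpec, delta: float) -> dict:
    loops = surface.boundary_loops()
    if len(loops) != 3:
        warnings.warn(f"expected 3 openings, found {len(loops)}")
    er, el = spec.branch_ends
    targets = {"MPA": np.array([0.0, 0.0, 0.0]), "RPA": er, "LPA": el}
    labels = {}
    for name, tgt in targets.items():
        dists = [
            np.linalg.norm(surface.vertices[loop].mean(axis=0) - tgt)
            for loop in loops
        ]
        labels[name] = int(np.argmin(dists))
    return labels


def _ground_truth(spec: BifurcationSpec, field: ImplicitBifurcation, delta: float) -> GroundTruth:
    b = spec.bifurcation_origin
    ur, ul = spec.branch_directions
    zhat = np.array([0.0, 0.0, 1.0])
    half_trunk = 3.2 * max(spec.trunk_radius_inlet, spec.trunk_radius_outlet)
    half_branch = 3.2 * max(spec.branch_radii)

    # trunk outlet: most distal clean station along the trunk axis; the
    # section can stay merged well past the axis junction, so scan up to
    # just below the branch ends
    er, el = spec.branch_ends
    smax_trunk = min(er[2], el[2]) - 2.0 * delta - 1.0
    s_out = _find_clean_station(
        field, np.zeros(3), zhat, 0.5 * spec.trunk_length, smax_trunk,
        half_trunk, toward_carina=+1.0)
    # branch inlets: most proximal clean stations along the branch axes
    s_rpa = _find_clean_station(
        field, b, ur, 1.0, spec.branch_lengths[0] - delta - 1.5, half_branch,
        toward_carina=-1.0)
    s_lpa = _find_clean_station(
        field, b, ul, 1.0, spec.branch_lengths[1] - delta - 1.5, half_branch,
        toward_carina=-1.0)

    # centerlines: trunk along z up to the outlet station, branches along
    # their axes from their clean inlet stations to the trimmed ends
    n_samp = 40
    centerlines = {
        "MPA": np.linspace([0, 0, delta], [0, 0, s_out], n_samp),
        "RPA": np.linspace(b + s_rpa * ur, spec.branch_ends[0] - delta * ur, n_samp),
        "LPA": np.linspace(b + s_lpa * ul, spec.branch_ends[1] - delta * ul, n_samp),
    }

    s_in = delta + 1.0  # just inside the trimmed inlet opening
    planes = {
        "MPA_inlet": _plane_record(
            field, np.array([0.0, 0.0, s_in]), zhat, s_in, half_trunk),
        "MPA_outlet": _plane_record(
            field, s_out * zhat, zhat, s_out, half_trunk),
        "RPA_inlet": _plane_record(field, b + s_rpa * ur, ur, s_rpa, half_branch),
        "LPA_inlet": _plane_record(field, b + s_lpa * ul, ul, s_lpa, half_branch),
    }
    # analytic cross-checks for stations away from the carina
    a_in = spec.trunk_radius_at(s_in)
    b_in = spec.ellipticity_trunk * a_in
    planes["MPA_inlet"]["analytic_csa_mm2"] = float(np.pi * a_in * b_in)
    planes["MPA_inlet"]["analytic_perimeter_mm"] = ellipse_perimeter(a_in, b_in)
    planes["MPA_inlet"]["analytic_maximal_diameter_mm"] = 2.0 * max(a_in, b_in)

    c_out = planes["MPA_outlet"]["center"]
    c_rpa = planes["RPA_inlet"]["center"]
    c_lpa = planes["LPA_inlet"]["center"]
    v1, v2 = c_rpa - c_out, c_lpa - c_out
    tri_area = 0.5 * float(np.linalg.norm(np.cross(v1, v2)))
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    lo, hi = field.bounding_box(pad=1.0)
    halfspaces = [
        (planes["MPA_outlet"]["origin"], -planes["MPA_outlet"]["normal"]),
        (planes["RPA_inlet"]["origin"], planes["RPA_inlet"]["normal"]),
        (planes["LPA_inlet"]["origin"], planes["LPA_inlet"]["normal"]),
    ]
    vol = voxel_volume(field, lo, hi, 0.3, halfspaces)

    bifurcation = {
        "area_mm2": tri_area,
        "angle_deg": angle,
        "volume_mm3": vol,
    }
    return GroundTruth(centerlines=centerlines, planes=planes,
                       bifurcation=bifurcation, spec=spec)


# ----------------------------------------------------------- test helpers


def cylinder_mesh(radius: float, length: float, pitch: float = 0.7,
                  axis=(0.0, 0.0, 1.0)) -> VesselSurface:
    """Open-ended circular tube along ``axis`` (both ends trimmed)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    def field(pts):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        d = pts @ axis
        radial = np.linalg.norm(pts - d[:, None] * axis[None, :], axis=1) - radius
        return np.maximum(radial, np.maximum(-d, d - length))

    u, v = _plane_basis(axis)
    pad = 2.0
    corners = []
    for du in (-radius - pad, radius + pad):
        for dv in (-radius - pad, radius + pad):
            for dz in (-pad, length + pad):
                corners.append(du * u + dv * v + dz * axis)
    corners = np.array(corners)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    surf = _marching_cubes_mesh(field, lo, hi, pitch)
    delta = 1.3 * pitch
    surf = clip_halfspace(surf, delta * axis, -axis)
    surf = clip_halfspace(surf, (length - delta) * axis, axis)
    return surf.compact()


def arc_tube_mesh(arc_radius: float, tube_radius: float,
                  angle_deg: float = 120.0, pitch: float = 0.7) -> VesselSurface:
    """Tube whose axis is a circular arc in the xz-plane, centred at origin."""
    half = np.radians(angle_deg) / 2.0

    def field(pts):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        rad = np.hypot(x, z)
        d_axis = np.hypot(rad - arc_radius, y) - tube_radius
        theta = np.arctan2(x, z)  # 0 at +z, grows toward +x
        ang_cap = (np.abs(theta) - half) * arc_radius
        return np.maximum(d_axis, ang_cap)

    pad = tube_radius + 2.0
    lo = np.array([-arc_radius - pad, -pad, -arc_radius - pad])
    hi = np.array([arc_radius + pad, pad, arc_radius + pad])
    surf = _marching_cubes_mesh(field, lo, hi, pitch)
    # trim the two angular end caps
    delta = 1.3 * pitch / arc_radius
    for sgn in (1.0, -1.0):
        th = sgn * (half - delta)
        origin = arc_radius * np.array([np.sin(th), 0.0, np.cos(th)])
        normal = sgn * np.array([np.cos(th), 0.0, -np.sin(th)])
        surf = clip_halfspace(surf, origin, normal)
    return surf.compact()
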