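"""Bifurcation-section metrics and the trunk dilation flag.

The bifurcation triangle is spanned by the three plane centre points
(trunk outlet, right inlet, left inlet): its area, the interior angle
at the trunk-outlet vertex, and the lumen volume enclosed between the
three planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pabifurc import units
from pabifurc.mesh import VesselSurface, clip_halfspace

__all__ = [
    "bifurcation_area",
    "bifurcation_angle",
    "bifurcation_volume",
    "DilationFlag",
    "dilation_flag",
]


def bifurcation_area(c_outlet, c_rpa, c_lpa) -> float:
    """Area of the 3-D triangle of plane centres, in 100 mm^2.

    Collinear points give 0.
    """
    c_outlet = np.asarray(c_outlet, dtype=float)
    v1 = np.asarray(c_rpa, dtype=float) - c_outlet
    v2 = np.asarray(c_lpa, dtype=float) - c_outlet
    return units.area_to_reported(0.5 * float(np.linalg.norm(np.cross(v1, v2))))


def bifurcation_angle(c_outlet, c_rpa, c_lpa) -> float:
    """Interior angle at the trunk-outlet vertex, degrees."""
    c_outlet = np.asarray(c_outlet, dtype=float)
    v1 = np.asarray(c_rpa, dtype=float) - c_outlet
    v2 = np.asarray(c_lpa, dtype=float) - c_outlet
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("coincident points: angle undefined")
    cosang = float(v1 @ v2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def bifurcation_volume(surface: VesselSurface, outlet_plane, rpa_plane, lpa_plane) -> float:
    """Lumen volume between the three planes, in 1000 mm^3.

    Each plane is an object with ``origin`` and ``normal`` attributes
    (normals pointing distally along their paths).  The surface region
    distal of the outlet plane and proximal of both branch planes is cut
    out, capped and integrated with the divergence theorem.
    """
    region = clip_halfspace(surface, outlet_plane.origin, -np.asarray(outlet_plane.normal))
    region = clip_halfspace(region, rpa_plane.origin, np.asarray(rpa_plane.normal), cap=True)
    region = clip_halfspace(region, lpa_plane.origin, np.asarray(lpa_plane.normal), cap=True)
    # cap the outlet cut last so earlier clips cannot slice through it
    region = clip_halfspace(
        region, outlet_plane.origin, -np.asarray(outlet_plane.normal), cap=True
    )
    if not region.is_watertight():
        raise ValueError("clipped bifurcation region is not watertight")
    vol = region.volume()
    if vol <= 0:
        raise ValueError("clipped bifurcation region has non-positive volume")
    return units.volume_to_reported(vol)


@dataclass(frozen=True)
class DilationFlag:
    """Trunk transverse diameter (mm) and its >29 mm dichotomy."""

    transverse_diameter_mm: float
    dilated: bool


def dilation_flag(transverse_diameter_mm: float) -> DilationFlag:
    """Strictly-greater-than-29 mm dilation dichotomy."""
    if transverse_diameter_mm <= 0:
        raise ValueError("transverse diameter must be positive")
    return DilationFlag(
        transverse_diameter_mm=float(transverse_diameter_mm),
        dilated=transverse_diameter_mm > units.DILATION_THRESHOLD_MM,
    )
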