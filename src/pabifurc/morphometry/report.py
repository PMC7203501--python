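"""One-call measurement of a vessel surface into a clinical-style row."""

from __future__ import annotations

from typing import Optional

import numpy as np

from pabifurc import units
from pabifurc.mesh import VesselSurface
from pabifurc.morphometry.bifurcation import (
    bifurcation_angle,
    bifurcation_area,
    bifurcation_volume,
    dilation_flag,
)
from pabifurc.morphometry.centerline import extract_centerline
from pabifurc.morphometry.planes import select_measurement_planes
from pabifurc.morphometry.section import cross_section

_PLANE_LABEL = {
    "MPA_inlet": "MPA inlet",
    "MPA_outlet": "MPA outlet",
    "RPA_inlet": "RPA inlet",
    "LPA_inlet": "LPA inlet",
}


def measure_surface(
    surface: VesselSurface,
    transverse_normal=(0.0, 0.0, 1.0),
    inlet: Optional[int] = None,
) -> dict:
    """Measure all reported morphometric quantities of one surface.

    Returns a flat dict keyed by the clinical column labels (scaled
    units) plus the dilation flag and the raw transverse diameter.  The
    transverse plane for the dilation measurement is taken normal to
    ``transverse_normal`` through the trunk mid-point (the mesh analogue
    of the CT transverse plane).
    """
    centerline = extract_centerline(surface, inlet=inlet)
    planes = select_measurement_planes(surface, centerline)

    row: dict = {}
    for pid, plane in planes.items():
        label = _PLANE_LABEL[pid]
        m = plane.metrics
        row[f"{label} CSA (100 mm2)"] = m.csa
        row[f"{label} hydraulic diameter (10 mm)"] = m.hydraulic_diameter
        row[f"{label} maximal diameter (10 mm)"] = m.maximal_diameter

    c_out = planes["MPA_outlet"].origin
    c_rpa = planes["RPA_inlet"].origin
    c_lpa = planes["LPA_inlet"].origin
    row["MPA bifurcation area (100 mm2)"] = bifurcation_area(c_out, c_rpa, c_lpa)
    row["MPA bifurcation angle (deg)"] = bifurcation_angle(c_out, c_rpa, c_lpa)
    row["MPA bifurcation volume (1000 mm3)"] = bifurcation_volume(
        surface, planes["MPA_outlet"], planes["RPA_inlet"], planes["LPA_inlet"]
    )

    # dilation: transverse-plane diameter at the trunk mid-point
    trunk = centerline.branches["MPA"]
    mid = trunk[len(trunk) // 2]
    sec = cross_section(surface, mid, np.asarray(transverse_normal, dtype=float))
    diameter_mm = sec.maximal_diameter_mm()
    flag = dilation_flag(diameter_mm)
    row["MPA transverse diameter (mm)"] = diameter_mm
    row["MPA dilation"] = int(flag.dilated)

    row["_stations_mm"] = {pid: p.station_mm for pid, p in planes.items()}
    return row
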