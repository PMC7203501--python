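"""Reporting-unit conventions.

All geometry is computed in millimetres internally.  Reported values use
the scaled units of the clinical tables: areas in 100 mm^2, lengths and
diameters in 10 mm, volumes in 1000 mm^3.  Conversion happens once, at
the reporting boundary.
"""

#: divisor taking mm^2 to reported area units (100 mm^2)
AREA_SCALE_MM2 = 100.0
#: divisor taking mm to reported length units (10 mm)
LENGTH_SCALE_MM = 10.0
#: divisor taking mm^3 to reported volume units (1000 mm^3)
VOLUME_SCALE_MM3 = 1000.0

#: transverse trunk diameter (mm) above which the vessel counts as dilated
DILATION_THRESHOLD_MM = 29.0


def area_to_reported(area_mm2: float) -> float:
    """mm^2 -> 100 mm^2."""
    return area_mm2 / AREA_SCALE_MM2


def length_to_reported(length_mm: float) -> float:
    """mm -> 10 mm."""
    return length_mm / LENGTH_SCALE_MM


def volume_to_reported(volume_mm3: float) -> float:
    """mm^3 -> 1000 mm^3."""
    return volume_mm3 / VOLUME_SCALE_MM3
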