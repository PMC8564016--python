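"""Unit conventions and conversion constants.

The library stores geometry and fluid quantities in SI (metres, square
metres, Pa, m^3/s).  Clinical units (mm, mm^2, mmHg, mL/s) appear only at
interfaces: geometry files, patient files, CSV reports and the CLI.
Volumetric flows are carried in mL/s inside :class:`~ffram.flow.FlowAssignment`
because that is the scale clinicians quote; pressure routines convert to
m^3/s at the call site via :data:`MLPS`.
"""

import math

#: metres per millimetre
MM = 1e-3
#: square metres per square millimetre
MM2 = 1e-6
#: Pa per mmHg (conventional mercury-column definition)
MMHG = 133.322387415
#: m^3/s per mL/s
MLPS = 1e-6

PI = math.pi


def area_from_radius(r: float) -> float:
    """Lumen area of a circular cross-section of radius ``r`` (same units²)."""
    return PI * r * r


def radius_from_area(a):
    """Equivalent circular radius for lumen area ``a`` (element-wise)."""
    return (a / PI) ** 0.5
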