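"""Unit conversions between field conventions and SI.

Measurements of samaras are conventionally reported in a mixed system —
lengths in cm (span, chord) or mm (wing thickness), mass in mg, planform
area in cm², speeds in cm s⁻¹, angular rates in rad s⁻¹ and angles in
degrees.  All table and CLI boundaries of this package use those field
units; internal aerodynamic computations run in SI.  Conversions are
centralized here so no other module hard-codes a factor.
"""

from __future__ import annotations

# length
CM_TO_M = 1e-2
MM_TO_M = 1e-3
M_TO_UM = 1e6

# mass
MG_TO_KG = 1e-6

# area
CM2_TO_M2 = 1e-4

# speed
CM_S_TO_M_S = 1e-2

#: standard gravitational acceleration, m s⁻²
G = 9.81

#: air density at laboratory conditions, kg m⁻³
RHO_AIR = 1.23


def cm_to_m(x: float) -> float:
    return x * CM_TO_M


def mm_to_m(x: float) -> float:
    return x * MM_TO_M


def mg_to_kg(x: float) -> float:
    return x * MG_TO_KG


def cm2_to_m2(x: float) -> float:
    return x * CM2_TO_M2


def cm_s_to_m_s(x: float) -> float:
    return x * CM_S_TO_M_S


def m_to_um(x: float) -> float:
    return x * M_TO_UM
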