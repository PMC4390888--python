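"""Unit conventions and physical constants shared by every module.

Internal convention: lengths in micrometres (um), volumes in femtolitres
(fL, numerically equal to um^3), areas in um^2, concentrations in mol/L,
time in seconds, membrane permeability quoted in cm/s.  All conversion
factors live here; no other module hard-codes one.
"""

AVOGADRO = 6.02214e23
"""Avogadro constant, 1/mol."""

FL_PER_UM3 = 1.0
"""1 um^3 is exactly 1 fL."""

L_PER_FL = 1e-15
"""Litres per femtolitre."""

ML_PER_L = 1e3
"""Millilitres per litre."""

UM_PER_CM = 1e4
"""Micrometres per centimetre."""

NM2_PER_UM2 = 1e6
"""Square nanometres per square micrometre."""


def cm_per_s_to_um_per_s(p: float) -> float:
    """Convert a permeability coefficient from cm/s to um/s."""
    return p * UM_PER_CM


def molar_to_molecules_per_fl(c: float) -> float:
    """Convert mol/L to absolute molecule count per femtolitre."""
    return c * AVOGADRO * L_PER_FL
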