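"""Spherical-vesicle geometry and occupancy arithmetic.

A micrometre-sized unilamellar vesicle is modelled as a sphere of
diameter ``d``: lumen volume ``V = (pi/6) d^3`` and membrane area
``A = pi d^2``.  The expected number of solute molecules captured at
membrane closure from a well-mixed solution is ``mu = N_A * C_bulk * V``,
the quantity every entrapment statistic in this package is built on.
Also provides vesicle number-concentration arithmetic from a total lipid
concentration and an area-per-lipid assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import AVOGADRO, L_PER_FL, ML_PER_L, NM2_PER_UM2

__all__ = [
    "VesicleSpec",
    "SoluteSpec",
    "MembraneSpec",
    "sphere_volume",
    "sphere_area",
    "diameter_from_volume",
    "expected_occupancy",
    "lipids_per_vesicle",
    "vesicle_number_concentration",
]


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere, fL, from its diameter in um.

    Parameters
    ----------
    diameter : float
        Sphere diameter in micrometres; must be positive.

    Returns
    -------
    float
        Volume in femtolitres (1 um^3 = 1 fL).  A 1.3 um vesicle holds
        1.15 fL.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return math.pi / 6.0 * diameter**3


def sphere_area(diameter: float) -> float:
    """Surface area of a sphere, um^2, from its diameter in um."""
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    return math.pi * diameter**2


def diameter_from_volume(volume: float) -> float:
    """Diameter (um) of the sphere with the given volume (fL)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class VesicleSpec:
    """Geometry of one spherical unilamellar vesicle.

    Attributes
    ----------
    diameter : float
        Diameter in um.
    volume : float
        Lumen volume in fL, derived from the diameter.
    membrane_area : float
        Membrane (great-sphere) area in um^2, derived.
    """

    diameter: float
    volume: float = field(init=False)
    membrane_area: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume", sphere_volume(self.diameter))
        object.__setattr__(self, "membrane_area", sphere_area(self.diameter))


@dataclass(frozen=True)
class SoluteSpec:
    """A dissolved macromolecule and its bulk concentration (mol/L)."""

    name: str
    bulk_concentration: float
    molecular_weight_kda: float | None = None

    def __post_init__(self) -> None:
        if self.bulk_concentration < 0:
            raise ValueError(
                f"bulk_concentration must be >= 0, got {self.bulk_concentration}"
            )


@dataclass(frozen=True)
class MembraneSpec:
    """Lipid packing of the bilayer: area per lipid head group (nm^2).

    The 0.72 nm^2 default is the standard fluid-phase value for
    phosphatidylcholine; it is an assumption of this package, not a
    measured property of any particular preparation, and should be set
    explicitly when a different lipid dominates.
    """

    area_per_lipid_nm2: float = 0.72
    leaflets: int = 2

    def __post_init__(self) -> None:
        if self.area_per_lipid_nm2 <= 0:
            raise ValueError("area_per_lipid_nm2 must be positive")
        if self.leaflets not in (1, 2):
            raise ValueError(f"leaflets must be 1 or 2, got {self.leaflets}")


def expected_occupancy(solute: SoluteSpec, vesicle: VesicleSpec) -> float:
    """Expected molecule count mu = N_A * C_bulk * V for one vesicle.

    For a 1 um vesicle in a 0.1 uM solution this is 31.5 molecules
    (commonly quoted rounded to 32).  Exactly linear in the bulk
    concentration and cubic in the diameter.
    """
    return AVOGADRO * solute.bulk_concentration * vesicle.volume * L_PER_FL


def lipids_per_vesicle(vesicle: VesicleSpec, membrane: MembraneSpec) -> float:
    """Number of lipid molecules forming one vesicle's bilayer.

    ``leaflets * membrane_area / area_per_lipid`` with the area converted
    to nm^2; curvature asymmetry between leaflets is ignored.
    """
    area_nm2 = vesicle.membrane_area * NM2_PER_UM2
    return membrane.leaflets * area_nm2 / membrane.area_per_lipid_nm2


def vesicle_number_concentration(
    lipid_concentration: float,
    vesicle: VesicleSpec,
    membrane: MembraneSpec,
) -> float:
    """Vesicle number concentration (vesicles/mL) at a given lipid molarity.

    Assumes all lipid (mol/L) is assembled into identical unilamellar
    vesicles of the given geometry.  Multiplying by a subpopulation
    fraction gives that subpopulation's number concentration; at 1 uM
    lipid and 1 um diameter a 0.1% subpopulation numbers ~10^5 per mL.
    """
    if lipid_concentration <= 0:
        raise ValueError("lipid_concentration must be positive")
    lipids_per_ml = AVOGADRO * lipid_concentration / ML_PER_L
    return lipids_per_ml / lipids_per_vesicle(vesicle, membrane)
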