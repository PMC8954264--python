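"""Mensuration of a single unilamellar vesicle.

A small unilamellar liposome is modelled as a spherical shell: an aqueous
core of diameter ``d - 2t`` wrapped in a lipid bilayer of thickness ``t``,
with ``d`` the *outer* diameter (the quantity dynamic light scattering
reports).  The number of lipid molecules in a vesicle follows from the
surface areas of the two leaflets and the cross-sectional area one lipid
head-group occupies.

These per-particle quantities are the building blocks of the suspension
level excluded-volume fraction: the cumulative core (or membrane) volume of
all vesicles divided by the total suspension volume, which sets the maximum
amount of drug a population can sequester at equilibrium.

All lengths are in nm, areas in nm^2, volumes in nm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Vesicle",
    "core_volume",
    "membrane_volume",
    "lipids_per_vesicle",
    "DEFAULT_BILAYER_THICKNESS_NM",
    "DEFAULT_AREA_PER_LIPID_NM2",
]

#: Typical DSPC-bilayer thickness (nm); configurable on every entry point.
DEFAULT_BILAYER_THICKNESS_NM = 5.0
#: Typical DSPC head-group area per lipid in one leaflet (nm^2); configurable.
DEFAULT_AREA_PER_LIPID_NM2 = 0.45

_SPHERE = math.pi / 6.0


@dataclass(frozen=True)
class Vesicle:
    """One unilamellar vesicle.

    Parameters
    ----------
    outer_diameter_nm
        Outer diameter of the vesicle (nm), as reported by DLS.
    bilayer_thickness_nm
        Thickness of the lipid bilayer (nm).  Default is a typical value
        for a DSPC:cholesterol membrane.
    area_per_lipid_nm2
        Area occupied by one lipid molecule in one leaflet (nm^2).
    """

    outer_diameter_nm: float
    bilayer_thickness_nm: float = DEFAULT_BILAYER_THICKNESS_NM
    area_per_lipid_nm2: float = DEFAULT_AREA_PER_LIPID_NM2

    def __post_init__(self) -> None:
        d, t, a = (
            self.outer_diameter_nm,
            self.bilayer_thickness_nm,
            self.area_per_lipid_nm2,
        )
        if not (t >= 0.0):
            raise ValueError(f"bilayer_thickness_nm must be >= 0, got {t}")
        if d < 2.0 * t:
            raise ValueError(
                "outer_diameter_nm must be >= 2 * bilayer_thickness_nm "
                f"(got d={d} nm, 2t={2.0 * t} nm): the core diameter d - 2t "
                "would be negative"
            )
        if not (a > 0.0):
            raise ValueError(f"area_per_lipid_nm2 must be > 0, got {a}")

    @property
    def core_diameter_nm(self) -> float:
        """Diameter of the aqueous core (nm); zero for a degenerate vesicle."""
        return self.outer_diameter_nm - 2.0 * self.bilayer_thickness_nm


def core_volume(v: Vesicle) -> float:
    """Aqueous core volume of one vesicle, (pi/6)(d - 2t)^3, in nm^3.

    Zero when the core is degenerate (d == 2t).
    """
    return _SPHERE * v.core_diameter_nm**3


def membrane_volume(v: Vesicle) -> float:
    """Lipid-shell volume of one vesicle, (pi/6)(d^3 - (d - 2t)^3), in nm^3.

    Zero when the bilayer has zero thickness.  ``core_volume`` and
    ``membrane_volume`` add up to the full sphere volume exactly.
    """
    return _SPHERE * (v.outer_diameter_nm**3 - v.core_diameter_nm**3)


def lipids_per_vesicle(v: Vesicle) -> float:
    """Number of lipid molecules forming one vesicle (both leaflets).

    The outer leaflet covers the sphere of diameter ``d`` and the inner
    leaflet the sphere of diameter ``d - 2t``; each lipid occupies
    ``area_per_lipid_nm2`` of its leaflet:

        N = (pi d^2 + pi (d - 2t)^2) / a
    """
    d, c = v.outer_diameter_nm, v.core_diameter_nm
    return math.pi * (d * d + c * c) / v.area_per_lipid_nm2
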