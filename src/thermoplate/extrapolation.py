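"""Tissue-scale heat extrapolation and capsule electron balance.

Two small calculations connect the per-cell calorimetry result to the
joint scale:

* *Tissue heat density* — per-cell total heat (uJ/cell) times areal
  chondrocyte density (cells/mm^2) gives heat per unit cartilage area
  (mJ/mm^2); multiplied by cartilage thickness (mm) it gives heat per
  unit depth in the sagittal plane (mJ/mm).  Comparing healthy and
  osteoarthritic densities/thicknesses quantifies how much metabolic
  heat capacity the degenerating tissue loses.

* *Electron balance* — each sealed capsule holds a fixed amount of O2;
  comparing the electrons the media's carbon sources can donate on
  complete oxidation (degree of reduction: glucose 24, pyruvate 10,
  glutamine 18 e-/mol) against the electrons the headspace O2 can accept
  (4 e-/mol) shows whether the culture is oxygen-limited (ratio > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Donor",
    "MediaComposition",
    "ElectronBalanceResult",
    "TissueParameters",
    "heat_per_area",
    "heat_per_depth",
    "donor_acceptor_ratio",
    "glucose_media",
    "glutamine_media",
    "HEALTHY_TISSUE",
    "OA_TISSUE",
]

#: capsule geometry (L): 656 uL capsule = 150 uL gel + 186 uL media + 320 uL air
CAPSULE_VOLUME_L = 656e-6
GEL_VOLUME_L = 150e-6
MEDIA_VOLUME_L = 186e-6
HEADSPACE_VOLUME_L = CAPSULE_VOLUME_L - GEL_VOLUME_L - MEDIA_VOLUME_L

#: ambient O2 solubility-equivalent concentration in the headspace,
#: elevation-corrected (mol/L)
O2_CONCENTRATION_M = 6.84e-3

GLUCOSE_MW = 180.156  # g/mol
SODIUM_PYRUVATE_MW = 110.04  # g/mol

ELECTRONS_PER_MOLE = {"glucose": 24, "pyruvate": 10, "glutamine": 18}
ELECTRONS_PER_O2 = 4


@dataclass(frozen=True)
class Donor:
    """One electron-donating carbon source in the media stock."""

    name: str
    concentration_M: float  # mol/L in the undiluted stock
    electrons_per_mole: int
    dilution_factor: float = 0.25  # 1 part stock to 3 parts PBS

    def __post_init__(self) -> None:
        if self.concentration_M < 0 or not 0 <= self.dilution_factor <= 1:
            raise ValueError(f"donor {self.name}: invalid concentration or dilution")
        if self.electrons_per_mole <= 0:
            raise ValueError(f"donor {self.name}: electrons_per_mole must be positive")


@dataclass(frozen=True)
class MediaComposition:
    """Capsule contents for the electron balance.

    ``liquid_volume_L`` is the volume that carries donor carbon at the
    (diluted) suspension-media concentrations; the default counts both
    the hydrogel and the supplemental media.
    """

    donors: tuple[Donor, ...]
    liquid_volume_L: float = GEL_VOLUME_L + MEDIA_VOLUME_L
    headspace_volume_L: float = HEADSPACE_VOLUME_L
    o2_concentration_M: float = O2_CONCENTRATION_M
    electrons_per_o2: int = ELECTRONS_PER_O2

    def __post_init__(self) -> None:
        if self.liquid_volume_L < 0 or self.headspace_volume_L < 0:
            raise ValueError("volumes must be >= 0")
        if self.electrons_per_o2 <= 0:
            raise ValueError("electrons_per_o2 must be a positive integer")


@dataclass(frozen=True)
class ElectronBalanceResult:
    donor_electrons_mol: float
    acceptor_electrons_mol: float
    ratio: float


@dataclass(frozen=True)
class TissueParameters:
    """Areal cell density (cells/mm^2) and cartilage thickness (mm)."""

    cell_density_per_mm2: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.cell_density_per_mm2 < 0 or self.thickness_mm < 0:
            raise ValueError("tissue parameters must be >= 0")


#: superficial-zone chondrocyte density and central medial femorotibial
#: cartilage thickness, healthy vs osteoarthritic human tissue
HEALTHY_TISSUE = TissueParameters(cell_density_per_mm2=4363.0, thickness_mm=3.9)
OA_TISSUE = TissueParameters(cell_density_per_mm2=1622.0, thickness_mm=3.68)


def heat_per_area(per_cell_heat_uJ: float, cell_density_per_mm2: float) -> float:
    """Heat per unit tissue area in mJ/mm^2 (uJ/cell x cells/mm^2 / 1000)."""
    if per_cell_heat_uJ < 0 or cell_density_per_mm2 < 0:
        raise ValueError("inputs must be >= 0")
    return per_cell_heat_uJ * cell_density_per_mm2 / 1000.0


def heat_per_depth(area_heat_mJ_per_mm2: float, thickness_mm: float) -> float:
    """Heat per unit depth in the sagittal plane, mJ/mm."""
    if area_heat_mJ_per_mm2 < 0 or thickness_mm < 0:
        raise ValueError("inputs must be >= 0")
    return area_heat_mJ_per_mm2 * thickness_mm


def donor_acceptor_ratio(media: MediaComposition) -> ElectronBalanceResult:
    """Electron donor-to-acceptor ratio of a sealed capsule.

    Donor electrons sum ``concentration x dilution x liquid volume x
    electrons/mol`` over carbon sources; acceptor electrons are the
    headspace O2 times 4.  A ratio above 1 means complete oxidation of
    the media carbon would exhaust the capsule's oxygen.
    """
    donor = sum(
        d.concentration_M * d.dilution_factor * media.liquid_volume_L * d.electrons_per_mole
        for d in media.donors
    )
    acceptor = media.o2_concentration_M * media.headspace_volume_L * media.electrons_per_o2
    if acceptor <= 0:
        raise ValueError("acceptor electrons must be positive")
    return ElectronBalanceResult(
        donor_electrons_mol=donor,
        acceptor_electrons_mol=acceptor,
        ratio=donor / acceptor,
    )


def _pyruvate(dilution: float = 0.25) -> Donor:
    return Donor(
        name="pyruvate",
        concentration_M=0.110 / SODIUM_PYRUVATE_MW,  # 110 mg/L sodium pyruvate
        electrons_per_mole=ELECTRONS_PER_MOLE["pyruvate"],
        dilution_factor=dilution,
    )


def glucose_media(dilution: float = 0.25) -> MediaComposition:
    """Glucose-enriched capsule media: 4.5 g/L glucose + 110 mg/L pyruvate stock."""
    glucose = Donor(
        name="glucose",
        concentration_M=4.5 / GLUCOSE_MW,
        electrons_per_mole=ELECTRONS_PER_MOLE["glucose"],
        dilution_factor=dilution,
    )
    return MediaComposition(donors=(glucose, _pyruvate(dilution)))


def glutamine_media(dilution: float = 0.25) -> MediaComposition:
    """Glutamine-enriched capsule media: 2 mM glutamine + 110 mg/L pyruvate stock."""
    glutamine = Donor(
        name="glutamine",
        concentration_M=2e-3,
        electrons_per_mole=ELECTRONS_PER_MOLE["glutamine"],
        dilution_factor=dilution,
    )
    return MediaComposition(donors=(glutamine, _pyruvate(dilution)))
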