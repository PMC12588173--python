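"""Innervation-density morphometry of the apical cochlea.

Simple, fully auditable arithmetic linking histological measurements to
neuron and hair-cell counts: cylinder-packing estimates of spiral-ganglion
(SG) soma numbers, linear scaling of counted myelinated axons to a longer
basilar-membrane (BM) span, inner-hair-cell (IHC) counts from a linear
density, innervation ratios, and percentage length fractions.

Rounding follows reporting conventions: packed-cell counts are floored
(a cylinder cannot hold a fraction more cells than its capacity), density
scalings use round-half-up, ratios are given to one decimal and fractions
to the nearest integer percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, InvalidInputError

__all__ = [
    "MorphometryParams",
    "estimate_neurons_cylinder",
    "scale_axon_count",
    "estimate_ihc_count",
    "innervation_ratio",
    "apical_fraction",
    "morphometry_summary",
]


def _round_half_up(x: float) -> int:
    # snap to 9 decimals first so products like 110*4.35 hit .5 exactly
    return int(math.floor(round(x, 9) + 0.5))


@dataclass(frozen=True)
class MorphometryParams:
    """Histological inputs for the innervation-density estimates.

    Defaults describe the apical human SG: type I somata of 22 um diameter
    packed in a helical cylinder 1.51 mm long and 200 um across; ~100 IHCs
    per mm; 3694 counted myelinated peripheral axons supplying the 4.35 mm
    apical turn.  All lengths in mm.
    """

    cell_diameter: float = 0.022
    cylinder_length: float = 1.51
    cylinder_diameter: float = 0.2
    packing_fraction: float = 1.0
    ihc_density: float = 100.0
    axon_count: int = 3694
    axon_ref_length: float = 4.35

    def __post_init__(self):
        if min(self.cell_diameter, self.cylinder_length, self.cylinder_diameter,
               self.axon_ref_length) <= 0:
            raise InvalidInputError("all lengths must be positive")
        if not (0 < self.packing_fraction <= 1):
            raise InvalidInputError("packing_fraction must be in (0, 1]")
        if self.ihc_density <= 0:
            raise InvalidInputError("ihc_density must be positive")
        if self.axon_count < 0:
            raise InvalidInputError("axon_count must be non-negative")


def estimate_neurons_cylinder(p: MorphometryParams) -> int:
    """Soma capacity of a cylinder: floor(packing * V_cylinder / V_soma).

    A pure volume-ratio estimate of how many spherical somata of diameter
    ``cell_diameter`` fit a cylinder of ``cylinder_length`` and
    ``cylinder_diameter``, scaled by ``packing_fraction`` (1.0 = pure volume
    ratio, no packing correction).
    """
    if not p.cell_diameter < p.cylinder_diameter:
        raise InvalidInputError("cell diameter must be smaller than cylinder diameter")
    v_cyl = math.pi * (p.cylinder_diameter / 2.0) ** 2 * p.cylinder_length
    v_cell = (4.0 / 3.0) * math.pi * (p.cell_diameter / 2.0) ** 3
    return int(math.floor(p.packing_fraction * v_cyl / v_cell))


def scale_axon_count(n: int, ref_length: float, target_length: float) -> int:
    """Scale a counted axon number from a reference BM span to a target span.

    Assumes constant neural density per mm of basilar membrane; rounds
    half-up to an integer count.
    """
    if ref_length <= 0 or target_length <= 0:
        raise DomainError("lengths must be positive")
    if n < 0:
        raise InvalidInputError("count must be non-negative")
    return _round_half_up(n * target_length / ref_length)


def estimate_ihc_count(density_per_mm: float, length_mm: float) -> int:
    """Inner-hair-cell count from a linear density (cells/mm) over a BM span."""
    if density_per_mm <= 0 or length_mm <= 0:
        raise DomainError("density and length must be positive")
    return _round_half_up(density_per_mm * length_mm)


def innervation_ratio(neurons: int, ihcs: int) -> float:
    """Afferent axons per inner hair cell, reported to one decimal."""
    if ihcs == 0:
        raise DomainError("IHC count must be non-zero")
    if ihcs < 0 or neurons < 0:
        raise InvalidInputError("counts must be non-negative")
    return _round_half_up(10.0 * neurons / ihcs) / 10.0


def apical_fraction(part_length: float, total_length: float) -> int:
    """Percentage of a total curvilinear length, to the nearest integer."""
    if total_length <= 0:
        raise DomainError("total length must be positive")
    if part_length < 0 or part_length > total_length:
        raise InvalidInputError("part length must lie in [0, total]")
    return _round_half_up(100.0 * part_length / total_length)


def morphometry_summary(
    p: MorphometryParams,
    apical_bm_length: float = 9.6,
    bm_total_length: float = 34.10,
    apical_sg_length: float = 1.37,
    sg_total_length: float = 14.73,
) -> pd.DataFrame:
    """One-table summary of the innervation-density estimates.

    Combines the cylinder-packing soma capacity, the axon-density scaling of
    the counted apical axons onto the apical BM span, the IHC count from the
    linear density, the resulting axons-per-IHC ratio and the apical length
    fractions.  The cylinder estimate is a capacity bound (no packing
    correction by default) and is reported alongside the density-scaled
    count rather than merged with it.
    """
    neurons_scaled = scale_axon_count(p.axon_count, p.axon_ref_length, apical_bm_length)
    neurons_cyl = estimate_neurons_cylinder(p)
    ihcs = estimate_ihc_count(p.ihc_density, apical_bm_length)
    rows = [
        ("apical_bm_length_mm", apical_bm_length),
        ("apical_bm_fraction_pct", apical_fraction(apical_bm_length, bm_total_length)),
        ("apical_sg_length_mm", apical_sg_length),
        ("apical_sg_fraction_pct", apical_fraction(apical_sg_length, sg_total_length)),
        ("axons_counted", p.axon_count),
        ("axon_ref_length_mm", p.axon_ref_length),
        ("neurons_density_scaled", neurons_scaled),
        ("neurons_cylinder_capacity", neurons_cyl),
        ("ihc_count", ihcs),
        ("axons_per_ihc", innervation_ratio(neurons_scaled, ihcs)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])
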