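"""Tissue organic carbon and tracer-C incorporation per specimen.

A specimen's tissue carbon pool (mol organic C) is either measured directly
(EA analysis of homogenized tissue) or, for sponges whose tissue could not
be analysed, estimated from body volume V (mL, water displacement) through
the allometry AFDM[g] = log10(V) * 0.265 and OC = 0.5 * AFDM.  Tracer-C
incorporation is the tissue's excess 13C over the unfed-conspecific
background, divided by the substrate atom fraction, standardized to feeding
time and tissue OC.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import CARBON_MOLAR_MASS, DEFAULT_CONSTANTS, IsotopeConstants
from .errors import (
    InvalidProvisionError,
    MissingBackgroundError,
    NonPositiveAFDMError,
)
from .isotopes import delta_to_atom_fraction, excess_carbon13, tracer_carbon

logger = logging.getLogger(__name__)

TAXA = ("bivalve", "hma_sponge", "lma_sponge", "ophiuroid")

#: Slope of the sponge volume -> ash-free-dry-mass allometry (g per log10 mL).
AFDM_SLOPE = 0.265
#: Organic carbon as a fraction of AFDM.
OC_PER_AFDM = 0.5
#: Fraction of provided tracer-C above which substrate depletion is flagged.
DEPLETION_WARN_PERCENT = 90.0


@dataclass
class Specimen:
    """One experimental animal.

    volume is mL (water displacement, soft tissue only for bivalves);
    tissue_oc is mol organic C; delta values are per-mil vs VPDB;
    feeding_hours is the duration of the substrate exposure.
    Background specimens (unfed conspecifics) have is_background=True and
    no substrate batch.
    """

    id: str
    taxon: str
    volume: float | None = None
    tissue_oc: float | None = None
    dry_mass: float | None = None
    tissue_delta13c: float | None = None
    background_delta13c: float | None = None
    is_background: bool = False
    substrate_batch_id: str | None = None
    feeding_hours: float | None = None

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}; expected one of {TAXA}")
        if self.is_background and self.substrate_batch_id:
            raise ValueError(
                f"background specimen {self.id} must not reference a substrate batch"
            )


def sponge_oc_from_volume(volume: float, log_base: str = "10") -> float:
    """Estimate sponge tissue organic carbon (mol C) from volume (mL).

    AFDM[g] = log(V) * 0.265 with log base 10 by default (log_base="e"
    selects the natural log), OC[g] = 0.5 * AFDM, converted to mol with
    12.011 g mol-1.

    Raises
    ------
    NonPositiveAFDMError
        If volume <= 1 mL (the log allometry gives AFDM <= 0).
    """
    if volume <= 1.0:
        raise NonPositiveAFDMError(
            f"volume must be > 1 mL for the log allometry, got {volume}"
        )
    if log_base == "10":
        afdm_g = np.log10(volume) * AFDM_SLOPE
    elif log_base == "e":
        afdm_g = np.log(volume) * AFDM_SLOPE
    else:
        raise ValueError(f"log_base must be '10' or 'e', got {log_base!r}")
    return OC_PER_AFDM * afdm_g / CARBON_MOLAR_MASS


def incorporation_rate(
    spec: Specimen,
    f_substrate: float,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> float:
    """Tissue tracer-C incorporation rate, umol C (mol OC)-1 h-1.

    The tissue pool (tissue_oc mol -> umol) times the atom-fraction excess
    of the tissue over its background gives excess 13C; division by the
    substrate atom fraction converts to tracer-C; standardization divides
    by tissue OC (mol) and feeding time (h).  Zero when the tissue delta
    equals the background delta.

    Raises
    ------
    MissingBackgroundError
        If the specimen has no background delta13C.
    """
    if spec.background_delta13c is None:
        raise MissingBackgroundError(
            f"specimen {spec.id} has no background delta13C"
        )
    for field in ("tissue_delta13c", "tissue_oc", "feeding_hours"):
        if getattr(spec, field) is None:
            raise ValueError(f"specimen {spec.id} missing {field}")
    f_tissue = delta_to_atom_fraction(spec.tissue_delta13c, constants)
    f_bg = delta_to_atom_fraction(spec.background_delta13c, constants)
    pool_umol = spec.tissue_oc * 1e6
    tracer_umol = tracer_carbon(
        excess_carbon13(f_tissue, f_bg, pool_umol), f_substrate
    )
    return tracer_umol / spec.tissue_oc / spec.feeding_hours


def percent_of_provided(incorporated: float, provided: float) -> float:
    """Incorporated tracer-C as a percentage of the tracer-C provided.

    Values above 90% trigger a substrate-depletion warning: the
    incorporation rate is then likely an underestimate because the feeding
    chamber ran out of labelled substrate.

    Raises
    ------
    InvalidProvisionError
        If provided <= 0.
    """
    if provided <= 0:
        raise InvalidProvisionError(f"provided tracer-C must be > 0, got {provided}")
    pct = 100.0 * incorporated / provided
    if pct > DEPLETION_WARN_PERCENT:
        warnings.warn(
            f"{pct:.1f}% of provided tracer-C incorporated: likely substrate "
            "depletion; the rate is probably an underestimate",
            stacklevel=2,
        )
    return pct
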