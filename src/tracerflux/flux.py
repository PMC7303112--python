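"""Net total-C and tracer-C fluxes from closed-chamber incubations.

A closed-cell incubation seals one animal (or no animal, for a control) in
a stirred chamber; the net flux of a dissolved or particulate pool is the
start-to-end concentration change times the chamber volume over the
duration.  Sign convention throughout: positive = release into the water,
negative = net uptake by the animal.  Respiration comes from the slope of
the logged O2 series times a respiratory quotient; tracer fluxes come from
the change in the excess-13C pool divided by the substrate atom fraction.
Animal rates are corrected by the mean rate of parallel no-organism
controls and standardized to tissue organic carbon.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .errors import (
    InfeasibleDesignError,
    InsufficientSeriesError,
    InvalidBiomassError,
    InvalidGeometryError,
    InvalidRefillError,
    MissingIsotopeError,
)
from .isotopes import delta_to_atom_fraction

logger = logging.getLogger(__name__)

SUBSTRATE_KINDS = ("dom", "bacteria", "diatom")

#: Printed atom-fraction ranges per substrate kind, used for validation of
#: fixtures and simulated batches.
SUBSTRATE_F13_RANGES = {
    "dom": (0.244, 0.255),
    "bacteria": (0.947, 0.965),
    "diatom": (0.292, 0.292),
}

STANDARD_RATE_UNITS = "umol C (mol OC)-1 h-1"
RAW_RATE_UNITS = "umol h-1"


@dataclass(frozen=True)
class SubstrateBatch:
    """A labelled food-source batch.

    carbon_concentration is the substrate-C concentration in the feeding
    chamber (uM C); atom_fraction is the batch's fractional 13C abundance.
    """

    id: str
    kind: str
    carbon_concentration: float
    atom_fraction: float

    def __post_init__(self) -> None:
        if self.kind not in SUBSTRATE_KINDS:
            raise ValueError(f"unknown substrate kind {self.kind!r}")
        if self.carbon_concentration <= 0:
            raise ValueError("carbon_concentration must be > 0 uM")
        if not 0 < self.atom_fraction <= 1:
            raise ValueError("atom_fraction must lie in (0, 1]")


@dataclass
class IncubationRecord:
    """One closed-cell incubation (animal chamber or no-organism control).

    Concentrations in uM, volumes in L, durations in h, delta values
    per-mil.  ``start_strategy`` is "separate_chamber" when the start
    sample came from an additionally prepared chamber, or
    "self_with_refill" when the start sample was drawn from the incubation
    chamber itself and the removed water replaced by refill water of known
    composition (the refill correction applies only to the latter).
    """

    chamber_id: str
    specimen_id: str | None
    group: str
    chamber_volume: float
    duration: float
    dic_start: float | None = None
    dic_end: float | None = None
    dic_d13c_start: float | None = None
    dic_d13c_end: float | None = None
    doc_start: float | None = None
    doc_end: float | None = None
    poc_start: float | None = None
    poc_end: float | None = None
    poc_d13c_start: float | None = None
    poc_d13c_end: float | None = None
    start_strategy: str = "separate_chamber"
    refill_volume: float = 0.0
    refill_dic: float | None = None
    refill_doc: float | None = None
    refill_poc: float | None = None
    o2_series: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chamber_volume <= 0 or self.duration <= 0:
            raise InvalidGeometryError(
                f"chamber {self.chamber_id}: volume and duration must be > 0"
            )
        if not 0 <= self.refill_volume < self.chamber_volume:
            raise InvalidRefillError(
                f"chamber {self.chamber_id}: refill volume must satisfy "
                "0 <= refill < chamber volume"
            )
        if self.start_strategy not in ("separate_chamber", "self_with_refill"):
            raise ValueError(
                f"unknown start_strategy {self.start_strategy!r}"
            )

    @property
    def is_control(self) -> bool:
        return not self.specimen_id

    def effective_start(self, pool: str) -> float:
        """Start concentration of a pool after any refill correction."""
        c = getattr(self, f"{pool}_start")
        if c is None:
            raise MissingIsotopeError(
                f"chamber {self.chamber_id}: no start concentration for {pool}"
            )
        if self.start_strategy == "self_with_refill" and self.refill_volume > 0:
            c_refill = getattr(self, f"refill_{pool}")
            if c_refill is None:
                raise MissingIsotopeError(
                    f"chamber {self.chamber_id}: refill {pool} concentration missing"
                )
            return refill_corrected_start(
                c, c_refill, self.refill_volume, self.chamber_volume
            )
        return c


@dataclass
class FluxResult:
    """One estimated flux for one chamber.

    ``rate`` is biomass-standardized (umol C (mol OC)-1 h-1) when
    ``units == STANDARD_RATE_UNITS``; ``raw_rate`` is the chamber-level
    rate in umol h-1.  Negative rates mean net uptake.
    """

    chamber_id: str
    specimen_id: str | None
    quantity: str  # respiration_total | poc_total | doc_total | respiration_tracer | poc_tracer
    raw_rate: float
    rate: float | None = None
    units: str = RAW_RATE_UNITS
    control_corrected: bool = False
    r_squared: float | None = None


def net_release_rate(
    c_start: float, c_end: float, volume: float, duration: float
) -> float:
    """Net release rate (umol h-1) from a start/end concentration pair.

    (c_end - c_start) * volume / duration; positive = release,
    negative = net uptake.

    Raises
    ------
    InvalidGeometryError
        If volume or duration is not strictly positive.
    """
    if volume <= 0 or duration <= 0:
        raise InvalidGeometryError("volume and duration must be > 0")
    return (c_end - c_start) * volume / duration


def refill_corrected_start(
    c_measured: float, c_refill: float, refill_volume: float, chamber_volume: float
) -> float:
    """Effective start concentration after replacing sampled water.

    Mixing balance: c_measured * (1 - r) + c_refill * r with
    r = refill_volume / chamber_volume.  The result is a convex
    combination, always between the two inputs.

    Raises
    ------
    InvalidRefillError
        If refill_volume is negative or >= chamber_volume.
    """
    if not 0 <= refill_volume < chamber_volume:
        raise InvalidRefillError(
            "refill_volume must satisfy 0 <= refill_volume < chamber_volume"
        )
    r = refill_volume / chamber_volume
    return c_measured * (1.0 - r) + c_refill * r


def oxygen_consumption_rate(
    o2_series, volume: float
) -> tuple[float, float]:
    """O2 consumption rate (umol O2 h-1) from a logged concentration series.

    Ordinary least squares of concentration (uM) on time (h); the
    consumption rate is minus the slope times the chamber volume, positive
    for consumption.  Returns ``(rate, r_squared)``.

    Raises
    ------
    InsufficientSeriesError
        If fewer than 3 points or the series spans no time.
    """
    arr = np.asarray(o2_series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InsufficientSeriesError("O2 series needs >= 3 (time, conc) points")
    t, c = arr[:, 0], arr[:, 1]
    if np.ptp(t) <= 0:
        raise InsufficientSeriesError("O2 series must span > 0 h")
    if volume <= 0:
        raise InvalidGeometryError("volume must be > 0")
    res = sps.linregress(t, c)
    return -res.slope * volume, res.rvalue**2


def respiration_from_oxygen(
    o2_rate: float, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> float:
    """Carbon respiration (umol C h-1) from O2 consumption (umol O2 h-1).

    C rate = O2 rate * respiratory quotient (default 1: identity).
    """
    return o2_rate * constants.respiratory_quotient


def tracer_release_rate(
    rec: IncubationRecord,
    pool: str,
    f_background: float | None,
    f_substrate: float,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> float:
    """Net tracer-C release rate (umol substrate-derived C h-1) for a pool.

    The excess-13C inventory of the pool at start and end is
    (F(delta) - F_background) * C * V; the tracer rate is the inventory
    change over the duration divided by the substrate atom fraction.
    ``pool`` is "dic" or "poc" (no tracer flux is defined for DOC).  When
    ``f_background`` is None the atom fraction of the chamber's own start
    sample is used, which controls for enrichment carried over from the
    feeding phase (then the start inventory is zero by construction).

    Raises
    ------
    MissingIsotopeError
        If concentration or delta13C is missing for the pool.
    """
    if pool not in ("dic", "poc"):
        raise ValueError(f"tracer flux defined for 'dic' and 'poc' only, got {pool!r}")
    d_start = getattr(rec, f"{pool}_d13c_start")
    d_end = getattr(rec, f"{pool}_d13c_end")
    c_end = getattr(rec, f"{pool}_end")
    if d_start is None or d_end is None or c_end is None:
        raise MissingIsotopeError(
            f"chamber {rec.chamber_id}: missing {pool} concentration or delta13C"
        )
    c_start = rec.effective_start(pool)
    f_start = delta_to_atom_fraction(d_start, constants)
    f_end = delta_to_atom_fraction(d_end, constants)
    if f_background is None:
        f_background = f_start
    excess_start = (f_start - f_background) * c_start * rec.chamber_volume
    excess_end = (f_end - f_background) * c_end * rec.chamber_volume
    return (excess_end - excess_start) / rec.duration / f_substrate


def control_corrected(rate: float, control_rates) -> float:
    """Subtract the mean no-organism control rate from an animal rate.

    Rates must have been computed with the same formula and pool.  An
    empty control list leaves the rate unchanged with a warning.
    """
    control_rates = list(control_rates)
    if not control_rates:
        warnings.warn("no control rates supplied; rate left uncorrected", stacklevel=2)
        return rate
    return rate - float(np.mean(control_rates))


def standardize_to_biomass(raw_rate: float, tissue_oc: float) -> float:
    """Standardize a chamber rate (umol h-1) to tissue OC (mol).

    Raises
    ------
    InvalidBiomassError
        If tissue_oc <= 0.
    """
    if tissue_oc <= 0:
        raise InvalidBiomassError(f"tissue_oc must be > 0 mol, got {tissue_oc}")
    return raw_rate / tissue_oc
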