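"""Per-animal carbon budgets and food-chain transfer arithmetic.

A budget row gathers, for one animal, the standardized total-C fluxes
(respiration, POC release, DOC release; their sum is the total-C turnover)
and the tracer-C fluxes (tissue incorporation, tracer respiration, tracer
POC release).  Tracer fractions partition the utilized tracer-C over those
three sinks; DOC is excluded because no tracer-DOC flux is measured.
The module also provides the derived ecological scalings: tissue-POC
turnover in percent per day, areal flux upscaling, and the food-chain
13C transfer efficiency from producer waste to consumer tissue.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

from .errors import (
    InvalidDenominatorError,
    InvalidDensityError,
    UnitMismatchError,
)
from .flux import STANDARD_RATE_UNITS, FluxResult

logger = logging.getLogger(__name__)

TOTAL_QUANTITIES = ("respiration_total", "poc_total", "doc_total")
TRACER_QUANTITIES = ("incorporation_tracer", "respiration_tracer", "poc_tracer")


@dataclass
class BudgetRow:
    """Standardized total-C and tracer-C fluxes for one animal.

    All rates in umol C (mol OC)-1 h-1.  ``tracer_fractions`` partitions
    the utilized tracer-C over incorporation, respiration and POC release
    (DOC excluded); it is None when any tracer term is negative or all are
    zero (flagged, not computed).
    """

    specimen_id: str
    respiration_total: float
    poc_total: float
    doc_total: float
    incorporation_tracer: float
    respiration_tracer: float
    poc_tracer: float
    taxon: str | None = None
    group: str | None = None
    total_turnover: float = field(init=False)
    tracer_fractions: dict | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.total_turnover = (
            self.respiration_total + self.poc_total + self.doc_total
        )
        terms = {
            "incorporation": self.incorporation_tracer,
            "respiration": self.respiration_tracer,
            "poc": self.poc_tracer,
        }
        total = sum(terms.values())
        if all(v >= 0 for v in terms.values()) and total > 0:
            self.tracer_fractions = {k: v / total for k, v in terms.items()}
        else:
            logger.info(
                "specimen %s: tracer fractions not computed "
                "(zero or negative tracer terms)",
                self.specimen_id,
            )


def assemble_budget(
    fluxes: dict[str, FluxResult] | list[FluxResult],
    incorporation: float,
    specimen_id: str | None = None,
    taxon: str | None = None,
    group: str | None = None,
) -> BudgetRow:
    """Assemble a :class:`BudgetRow` from standardized flux results.

    ``fluxes`` maps quantity names (respiration_total, poc_total,
    doc_total, respiration_tracer, poc_tracer) to :class:`FluxResult`
    objects; ``incorporation`` is the tissue tracer-C incorporation rate in
    the same units.  Missing DOC is treated as zero release.

    Raises
    ------
    UnitMismatchError
        If any component is not standardized to umol C (mol OC)-1 h-1.
    """
    if not isinstance(fluxes, dict):
        fluxes = {f.quantity: f for f in fluxes}
    for f in fluxes.values():
        if f.units != STANDARD_RATE_UNITS or f.rate is None:
            raise UnitMismatchError(
                f"flux {f.quantity} for {f.chamber_id} is not standardized "
                f"({f.units})"
            )
    if specimen_id is None:
        ids = {f.specimen_id for f in fluxes.values() if f.specimen_id}
        if len(ids) != 1:
            raise ValueError("ambiguous specimen_id; pass it explicitly")
        specimen_id = ids.pop()

    def rate(q: str, required: bool = True) -> float:
        if q not in fluxes:
            if required:
                raise ValueError(f"missing flux {q} for specimen {specimen_id}")
            return 0.0
        return fluxes[q].rate

    return BudgetRow(
        specimen_id=specimen_id,
        respiration_total=rate("respiration_total"),
        poc_total=rate("poc_total"),
        doc_total=rate("doc_total", required=False),
        incorporation_tracer=incorporation,
        respiration_tracer=rate("respiration_tracer"),
        poc_tracer=rate("poc_tracer"),
        taxon=taxon,
        group=group,
    )


def tissue_poc_turnover(poc_rate: float) -> float:
    """POC release as percent of tissue carbon per day.

    A standardized rate of r umol C (mol OC)-1 h-1 releases
    r * 24 * 1e-6 mol per mol tissue C per day, i.e. r * 24e-4 percent.
    """
    return poc_rate * 24.0 * 1e-6 * 100.0


def areal_flux(per_individual_rate: float, density: float) -> float:
    """Upscale an individual rate to an areal flux (umol C m-2 h-1).

    Raises
    ------
    InvalidDensityError
        If density < 0.
    """
    if density < 0:
        raise InvalidDensityError(f"density must be >= 0, got {density}")
    return per_individual_rate * density


def round_to_sig_figs(value: float, n: int = 2) -> float:
    """Round to ``n`` significant figures (report convention for areal fluxes)."""
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (n - 1))


@dataclass
class FoodChainRecord:
    """Aggregated 13C budget of the experimental food chain.

    Fecal 13C produced by the bivalves and 13C incorporated by the
    ophiuroid consumers, both in umol over the experimental period (days),
    normalized to the same window before ratioing.
    """

    producer_ids: list[str]
    consumer_ids: list[str]
    fecal_13c_produced: float
    consumer_13c_incorporated: float
    period: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0 d")
        if self.fecal_13c_produced < 0 or self.consumer_13c_incorporated < 0:
            raise ValueError("13C amounts must be >= 0")


def transfer_efficiency(rec: FoodChainRecord) -> float:
    """Percent of producer (pseudo-)fecal 13C incorporated by the consumers.

    Raises
    ------
    InvalidDenominatorError
        If no fecal 13C was produced.
    """
    if rec.fecal_13c_produced <= 0:
        raise InvalidDenominatorError("fecal 13C production must be > 0")
    eff = 100.0 * rec.consumer_13c_incorporated / rec.fecal_13c_produced
    if eff > 100.0:
        warnings.warn(
            f"transfer efficiency {eff:.1f}% exceeds 100%: consumer "
            "incorporation exceeds fecal production (mass-balance violation)",
            stacklevel=2,
        )
    return eff


def daily_supply_total(per_day: float, n_cycles: int) -> float:
    """Total substrate supply over repeated feeding cycles (umol C).

    per_day * n_cycles; one cycle is the identity.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    return per_day * n_cycles
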