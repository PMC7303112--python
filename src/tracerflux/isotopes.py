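"""Conversions between delta notation, atom fraction and excess 13C.

Delta notation expresses a sample's 13C/12C ratio relative to the VPDB
standard in per-mil:  R_sample = (delta/1000 + 1) * R_VPDB.  The atom
fraction F = R / (1 + R) is the fraction of carbon atoms that are 13C and
is the linear currency for isotope mass balance: excess 13C in a pool of C
micromoles is (F_sample - F_background) * C, and dividing the excess by the
atom fraction of a labelled substrate converts it to substrate-derived
("tracer") carbon.

All functions accept scalars or numpy arrays; amounts are in umol C,
fractions are dimensionless in [0, 1), delta values are per-mil.
"""
from __future__ import annotations

import logging

import numpy as np

from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .errors import (
    InvalidAmountError,
    InvalidDeltaError,
    InvalidFractionError,
    InvalidSubstrateFractionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "excess_carbon13",
    "tracer_carbon",
]


def delta_to_atom_fraction(delta, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert delta13C (per-mil vs VPDB) to 13C atom fraction.

    F = ((delta/1000 + 1) * R) / (1 + (delta/1000 + 1) * R)

    Raises
    ------
    InvalidDeltaError
        If any delta <= -1000 (the implied isotope ratio would be <= 0).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise InvalidDeltaError(
            f"delta13C must be > -1000 per-mil, got min {delta.min()}"
        )
    ratio = (delta / 1000.0 + 1.0) * constants.r_vpdb
    frac = ratio / (1.0 + ratio)
    return frac if frac.ndim else float(frac)


def atom_fraction_to_delta(fraction, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Invert :func:`delta_to_atom_fraction`: atom fraction -> per-mil.

    Raises
    ------
    InvalidFractionError
        If any fraction lies outside the open interval (0, 1).
    """
    fraction = np.asarray(fraction, dtype=float)
    if np.any((fraction <= 0.0) | (fraction >= 1.0)):
        raise InvalidFractionError("atom fraction must lie strictly in (0, 1)")
    ratio = fraction / (1.0 - fraction)
    delta = (ratio / constants.r_vpdb - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def excess_carbon13(f_sample, f_background, carbon_amount):
    """Excess 13C (umol) in a pool above its isotopic background.

    E = (F_sample - F_background) * C.  Negative excess (sample below
    background, possible under measurement noise) is propagated unclipped
    with a warning, preserving mass balance.

    Raises
    ------
    InvalidAmountError
        If any carbon_amount < 0.
    """
    f_sample = np.asarray(f_sample, dtype=float)
    f_background = np.asarray(f_background, dtype=float)
    carbon_amount = np.asarray(carbon_amount, dtype=float)
    if np.any(carbon_amount < 0.0):
        raise InvalidAmountError("carbon_amount must be >= 0 umol")
    excess = (f_sample - f_background) * carbon_amount
    if np.any(excess < 0.0):
        logger.warning(
            "negative excess 13C (sample below background); propagated unclipped"
        )
    return excess if excess.ndim else float(excess)


def tracer_carbon(excess_13c, f_substrate):
    """Convert excess 13C (umol) to substrate-derived carbon (umol).

    tracer_C = excess_13C / F_substrate; equals the excess when the
    substrate is isotopically pure (F = 1).

    Raises
    ------
    InvalidSubstrateFractionError
        If any substrate fraction is outside (0, 1].
    """
    excess_13c = np.asarray(excess_13c, dtype=float)
    f_substrate = np.asarray(f_substrate, dtype=float)
    if np.any((f_substrate <= 0.0) | (f_substrate > 1.0)):
        raise InvalidSubstrateFractionError(
            "substrate atom fraction must lie in (0, 1]"
        )
    out = excess_13c / f_substrate
    return out if out.ndim else float(out)
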