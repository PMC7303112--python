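"""Physical constants shared by all isotope conversions.

The carbon-isotope reference is Vienna Pee Dee Belemnite (VPDB) with a
13C/12C ratio of 0.0111802.  Respiration is converted from oxygen
consumption with a respiratory quotient (mol C respired per mol O2
consumed) of 1 unless overridden.
"""
from __future__ import annotations

from dataclasses import dataclass

#: Atomic mass of carbon, g mol-1.
CARBON_MOLAR_MASS = 12.011

R_VPDB_DEFAULT = 0.0111802
RESPIRATORY_QUOTIENT_DEFAULT = 1.0


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants in force for one analysis.

    Parameters
    ----------
    r_vpdb : float
        13C/12C isotope ratio of the VPDB standard (dimensionless, > 0).
    respiratory_quotient : float
        mol C respired per mol O2 consumed (> 0).
    """

    r_vpdb: float = R_VPDB_DEFAULT
    respiratory_quotient: float = RESPIRATORY_QUOTIENT_DEFAULT

    def __post_init__(self) -> None:
        if self.r_vpdb <= 0:
            raise ValueError(f"r_vpdb must be > 0, got {self.r_vpdb}")
        if self.respiratory_quotient <= 0:
            raise ValueError(
                f"respiratory_quotient must be > 0, got {self.respiratory_quotient}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "IsotopeConstants":
        """Build constants from a config mapping; unknown keys rejected."""
        if not mapping:
            return cls()
        allowed = {"r_vpdb", "respiratory_quotient"}
        unknown = set(mapping) - allowed
        if unknown:
            from .errors import ConfigError

            raise ConfigError(f"unknown constants keys: {sorted(unknown)}")
        return cls(**mapping)


DEFAULT_CONSTANTS = IsotopeConstants()
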