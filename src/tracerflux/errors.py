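"""Exception hierarchy for tracerflux.

Every domain-level failure derives from :class:`TracerFluxError` so callers
can catch pipeline problems without swallowing programming errors.
"""


class TracerFluxError(ValueError):
    """Base class for all tracerflux domain errors."""


class InvalidDeltaError(TracerFluxError):
    """delta13C <= -1000 per-mil implies a non-positive isotope ratio."""


class InvalidFractionError(TracerFluxError):
    """Atom fraction outside the open interval (0, 1)."""


class InvalidAmountError(TracerFluxError):
    """Negative carbon amount passed where a pool size is required."""


class InvalidSubstrateFractionError(TracerFluxError):
    """Substrate atom fraction must lie in (0, 1]."""


class NonPositiveAFDMError(TracerFluxError):
    """Sponge volume <= 1 mL makes the log-allometry non-positive."""


class MissingBackgroundError(TracerFluxError):
    """No background delta13C available for a specimen's taxon."""


class InvalidProvisionError(TracerFluxError):
    """Provided tracer-C must be strictly positive."""


class InvalidGeometryError(TracerFluxError):
    """Chamber volume or incubation duration must be strictly positive."""


class InvalidRefillError(TracerFluxError):
    """Refill volume must satisfy 0 <= refill < chamber volume."""


class InsufficientSeriesError(TracerFluxError):
    """O2 regression needs >= 3 time points spanning a positive interval."""


class MissingIsotopeError(TracerFluxError):
    """Start or end delta13C missing for a tracer-flux pool."""


class InvalidBiomassError(TracerFluxError):
    """Tissue organic carbon must be strictly positive to standardize."""


class UnitMismatchError(TracerFluxError):
    """Budget components carry inconsistent units."""


class InvalidDensityError(TracerFluxError):
    """Population density cannot be negative."""


class InvalidDenominatorError(TracerFluxError):
    """Zero or negative fecal 13C production in a transfer-efficiency ratio."""


class InvalidInputError(TracerFluxError):
    """Malformed sample passed to a statistical test."""


class InfeasibleDesignError(TracerFluxError):
    """A simulated design exhausts a pool (named in the message)."""


class SchemaError(TracerFluxError):
    """A CSV table violates its schema (file, row and column in message)."""


class LinkError(TracerFluxError):
    """A cross-table reference does not resolve."""


class ConfigError(TracerFluxError):
    """Unknown or invalid configuration key."""
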