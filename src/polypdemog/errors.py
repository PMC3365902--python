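"""Exception hierarchy for the demographic pipeline.

``CensoredLength`` is deliberately *not* an error in the ordinary sense: it is
the signal raised when a corallite is at or beyond the asymptotic length and
therefore cannot be aged by inverting the growth curve.  Callers that age whole
populations catch it and flag the record instead of aborting.
"""


class PolypdemogError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PolypdemogError, ValueError):
    """A simulation or pipeline configuration value is invalid."""


class InsufficientDataError(PolypdemogError, ValueError):
    """Too few records, age classes, or regression points to fit."""


class NonConvergentGrowthError(PolypdemogError, ValueError):
    """Ford-Walford slope outside (0, 1): the sample does not show asymptotic growth."""


class CensoredLength(PolypdemogError):
    """Length at or above the asymptote; age is right-censored, not defined."""

    def __init__(self, length: float, l_inf: float):
        self.length = length
        self.l_inf = l_inf
        super().__init__(
            f"length {length:g} mm >= asymptotic length {l_inf:g} mm; age is censored"
        )


class MissingMassError(PolypdemogError, ValueError):
    """Observed biomass requested but some records lack a mass measurement."""


class UndefinedSummaryError(PolypdemogError, ValueError):
    """A demographic summary is undefined (e.g. zero total biomass)."""


class UndefinedCorrelationError(PolypdemogError, ValueError):
    """Pearson correlation undefined because a variable is constant."""


class SchemaError(PolypdemogError, ValueError):
    """An input file is missing mandatory columns."""


class CoverageError(PolypdemogError, ValueError):
    """A temperature series does not cover enough days for the requested statistic."""
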