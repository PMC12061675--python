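"""Exception hierarchy for stemgrowth."""


class StemGrowthError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(StemGrowthError, ValueError):
    """A Richards parameter violates its domain (a, b, c, d must all be > 0)."""


class InsufficientDataError(StemGrowthError, ValueError):
    """A stem series has too few (or too degenerate) points to fit."""


class UnreachableHeightError(StemGrowthError, ValueError):
    """Requested stem height is at or above the curve's asymptote."""


class InternalConsistencyError(StemGrowthError, RuntimeError):
    """Closed-form and numeric trait computations disagree beyond tolerance."""


class WeatherGapError(StemGrowthError, ValueError):
    """The daily weather record has a gap in its day sequence."""


class CoverageError(StemGrowthError, ValueError):
    """A measurement day is not covered by the weather record."""


class SchemaError(StemGrowthError, ValueError):
    """An input table is missing a required column or has a malformed value."""


class NonEstimableError(StemGrowthError, ValueError):
    """A statistical model cannot be estimated from the data provided."""
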