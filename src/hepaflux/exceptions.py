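"""Exception hierarchy for hepaflux.

All errors raised by the library derive from :class:`HepafluxError` so callers
can catch the whole family; most also derive from the matching builtin
(``ValueError`` etc.) so generic handling keeps working.
"""


class HepafluxError(Exception):
    """Base class for all hepaflux errors."""


class InvalidMeasurementError(HepafluxError, ValueError):
    """A raw measurement vector is unusable (all-zero, negative entries, wrong length)."""


class ConfigurationError(HepafluxError, ValueError):
    """A configuration value (fragment formula, abundance table, closure name) is invalid."""


class ChannelMismatchError(HepafluxError, ValueError):
    """Two derivative channels that must describe the same analyte do not."""


class DomainError(HepafluxError, ValueError):
    """An input is outside the mathematical domain of an operation (e.g. p > 1, d <= 0)."""


class IndeterminateError(HepafluxError, ValueError):
    """A ratio-based quantity cannot be formed because its denominator is below the noise floor."""

    def __init__(self, message: str, floor: float | None = None):
        super().__init__(message)
        self.floor = floor


class InfeasibleParametersError(HepafluxError, ValueError):
    """An isotope parameter set implies a negative flux under the chosen closure.

    Carries the offending value so per-animal reports can show how far the
    parameters are from feasibility.
    """

    def __init__(self, message: str, value: float):
        super().__init__(message)
        self.value = value


class DesignError(HepafluxError, ValueError):
    """The group design is unusable for the requested statistics (e.g. an empty cell)."""


class SchemaError(HepafluxError, ValueError):
    """An input table does not match the expected long-format sample schema."""
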