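"""Exception hierarchy shared across the package."""

__all__ = [
    "MinutecostError",
    "InvalidParameterError",
    "UndefinedRatioError",
    "SchemaError",
    "ConfigurationError",
]


class MinutecostError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MinutecostError, ValueError):
    """A numeric argument violates its precondition."""


class UndefinedRatioError(MinutecostError, ZeroDivisionError):
    """A cost-effectiveness ratio has a zero denominator (no gain difference)."""


class SchemaError(MinutecostError, ValueError):
    """An input file violates its schema; message names the offending row/column."""


class ConfigurationError(MinutecostError, ValueError):
    """An analysis configuration is incomplete or inconsistent."""
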