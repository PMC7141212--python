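"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: ``ConfigError`` -> 2,
``DataError`` -> 3, anything else -> 1.
"""


class MitodetectError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(MitodetectError):
    """A box or regression vector violates its geometric invariants."""


class ConfigError(MitodetectError):
    """A configuration value is out of range, missing, or unknown."""


class DataError(MitodetectError):
    """An input file or table is malformed or inconsistent."""


class CalibrationRequiredError(MitodetectError):
    """An operation needs a calibrated cascade/fusion config that was not supplied."""
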