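"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes): data
errors, raised when the input signals or derived quantities are unusable,
and configuration errors, raised when parameters or file metadata are
inconsistent before any analysis starts.
"""


class AmapError(Exception):
    """Base class for all package errors."""


class DataError(AmapError):
    """The data cannot support the requested analysis (CLI exit code 1)."""


class ConfigError(AmapError):
    """Parameters, schema or metadata are invalid (CLI exit code 2)."""


class SchemaError(ConfigError):
    """Sidecar/CSV structure violates the declared schema."""


class ParseError(DataError):
    """A sample value could not be parsed; message carries the row index."""


class DegenerateChannelError(DataError):
    """A channel is flat/degenerate (zero envelope, < k distinct values)."""


class NoGaitDetectedError(DataError):
    """No threshold crossings found in the vertical ground reaction force."""


class EventSequenceError(DataError):
    """Heel-strike/toe-off alternation cannot be established."""


class InsufficientDataError(DataError):
    """Fewer complete strides/observations than the operation requires."""


class DegenerateProfileError(DataError):
    """A normative cell has zero spread; message names the cell."""


class MismatchError(DataError):
    """Subject and normative profile disagree on muscles or regions."""


class UndefinedCorrelationError(DataError):
    """A correlation is requested on a zero-variance variable."""


class UndefinedPropulsionError(DataError):
    """Both legs have zero propulsive impulse."""


class DomainError(ConfigError):
    """A parameter is outside its physical/mathematical domain."""
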