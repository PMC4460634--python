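"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: config errors -> 2, data/format
errors -> 3, internal assertion failures -> 4.
"""


class GrnGpeaError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ConfigError(GrnGpeaError):
    """Invalid parameter value or malformed run configuration."""

    exit_code = 2


class DataError(GrnGpeaError):
    """Input data violates a documented precondition (domain error)."""

    exit_code = 3


class FormatError(DataError):
    """A file could not be parsed; carries file/line context in the message."""


class GenerationError(GrnGpeaError):
    """A synthetic-data generator could not satisfy its constraints."""

    exit_code = 3
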