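"""Exception types shared across the pipeline."""


class GaitDecodeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GaitDecodeError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(GaitDecodeError, ValueError):
    """Not enough samples/observations for the requested computation."""


class MissingChannelError(GaitDecodeError, KeyError):
    """A required marker or recording channel is absent."""


class FormatError(GaitDecodeError, IOError):
    """An on-disk file does not match the declared format."""


class UndefinedStatisticError(GaitDecodeError, ValueError):
    """A statistic is undefined for the given input (e.g. constant series)."""
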