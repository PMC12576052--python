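"""Exception hierarchy for qvmeth.

Every recoverable per-locus condition (window off the contig edge,
un-encodable reference context, too few covering reads) has its own type so
that pipeline code can skip the locus and log the reason instead of aborting.
"""


class QvmethError(Exception):
    """Base class for all qvmeth errors."""


class ParseError(QvmethError):
    """Malformed input table; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class WindowOutOfBoundsError(QvmethError):
    """Requested reference window extends past the contig boundary."""


class ContextUnencodableError(QvmethError):
    """Reference context contains a base outside {A, C, G, T}."""


class EmptyPileupError(QvmethError):
    """Operation requires at least one read in the pileup."""


class InsufficientDepthError(QvmethError):
    """Operation requires more reads than the pileup contains."""


class InsufficientDataError(QvmethError):
    """Too few training loci to fit a model."""


class LayoutError(QvmethError):
    """Feature-vector layout or shape does not match expectations."""


class AlignmentMismatchError(QvmethError):
    """Features and labels could not be aligned one-to-one."""


class NoDataError(QvmethError):
    """A summary was requested over an empty collection of values."""


class ConfigError(QvmethError):
    """Invalid simulation or run configuration."""
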