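"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`KelppopError`
so drivers can distinguish analysis failures from programming bugs.
"""


class KelppopError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(KelppopError):
    """Rows of an alignment differ in length."""


class DuplicateIdError(KelppopError):
    """Sequence identifiers are not unique."""


class EmptyInputError(KelppopError):
    """An input file or collection holds no records."""


class CoordinateError(KelppopError):
    """A 1-based coordinate falls outside the alignment."""


class IdMismatchError(KelppopError):
    """Strict concatenation over unequal identifier sets."""


class ArgumentError(KelppopError, ValueError):
    """Invalid argument combination (empty/overlapping groups, bad window)."""


class UndefinedPairError(KelppopError):
    """A sequence pair shares zero comparable (both non-missing) sites."""


class SaturationError(KelppopError):
    """Distance-correction logarithm undefined (p too large for the model)."""


class UndefinedStatisticError(KelppopError):
    """A differentiation statistic's denominator is zero."""


class InsufficientSignalError(KelppopError):
    """Too few informative sites for a recombination scan."""


class ConfigError(KelppopError):
    """Invalid simulation or pipeline configuration."""
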