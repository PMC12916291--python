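"""Exception hierarchy for ildscan.

Every error raised by the library derives from :class:`IldscanError` so that
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class IldscanError(Exception):
    """Base class for all ildscan-specific errors."""


class AlignmentFormatError(IldscanError):
    """Alignment records are malformed (e.g. unequal sequence lengths)."""


class DuplicateIdentifierError(IldscanError):
    """Two alignment records share the same identifier."""


class EmptyInputError(IldscanError):
    """An input file or container holds no usable records."""


class CoordinateError(IldscanError):
    """A genomic coordinate lies outside the contig or gene bounds."""


class UndefinedLDError(IldscanError):
    """r^2 is undefined for a pair (monomorphic among jointly called haplotypes)."""


class EmptyCurveError(IldscanError):
    """No valid site pairs were available to build an LD decay curve."""


class InsufficientDataError(IldscanError):
    """Too few populated bins (or sites) to compute the requested quantity."""


class DegenerateScanError(IldscanError):
    """Genome-wide standardization is impossible (zero variance or too few windows)."""


class ConditioningError(IldscanError):
    """The beneficial allele failed to establish within the configured cap."""


class UsageError(IldscanError):
    """Invalid user-facing argument (unknown scenario name, bad grouping, ...)."""
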