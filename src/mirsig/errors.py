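"""Exception hierarchy for the mirsig pipeline.

Every error raised by the package derives from :class:`MirsigError`, so callers
can catch one base class at a pipeline boundary while tests discriminate the
specific failure modes.
"""


class MirsigError(Exception):
    """Base class for all mirsig errors."""


class DuplicateIdError(MirsigError):
    """A miRNA or sample identifier occurs more than once."""


class MalformedCountError(MirsigError):
    """A count cell is negative, non-numeric, or not an integer."""


class EmptyInputError(MirsigError):
    """An input table is empty or below the minimal usable size."""


class AnnotationParseError(MirsigError):
    """A sample annotation row cannot be parsed (bad node status or Gleason)."""


class MissingAnnotationError(MirsigError):
    """A sample present in the count matrix has no annotation."""


class AlignmentError(MirsigError):
    """Two aligned structures (counts / factors / annotations) disagree."""


class ZeroLibraryError(MirsigError):
    """A sample has a zero total read count."""


class NormalizationError(MirsigError):
    """A normalization method cannot be computed on this matrix."""


class GroupSizeError(MirsigError):
    """A comparison group is empty or too small for the requested test."""


class DomainError(MirsigError):
    """A numeric argument lies outside its mathematical domain."""


class SetOverlapError(MirsigError):
    """The two signature miRNA sets overlap."""


class ConstantInputError(MirsigError):
    """A rank correlation was requested on a constant vector."""


class GleasonInsufficientError(MirsigError):
    """Fewer than 3 samples carry a Gleason score."""


class SpecValidationError(MirsigError):
    """A synthetic-data specification violates its invariants."""


class PipelineConfigError(MirsigError):
    """A pipeline configuration file is invalid or has unknown keys."""
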