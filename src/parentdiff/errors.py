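"""Exception types shared across the pipeline."""


class ParentDiffError(Exception):
    """Base class for all package errors."""


class ValidationError(ParentDiffError, ValueError):
    """A record or parameter violates its declared invariants."""


class ReferenceMismatchError(ParentDiffError, ValueError):
    """A call's stated reference allele disagrees with the reference sequence,
    or two parents disagree on the reference allele at one site."""


class GeneModelError(ParentDiffError, ValueError):
    """A gene model is structurally invalid (e.g. CDS length not divisible by 3)."""


class InsufficientDataError(ParentDiffError, ValueError):
    """Too few observations to run the requested statistical procedure."""


class SizingError(ParentDiffError, ValueError):
    """A simulated chromosome cannot host the requested gene content."""


class UndefinedRatioError(ParentDiffError, ZeroDivisionError):
    """An aggregate ratio has a zero denominator (e.g. mean dS = 0)."""
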