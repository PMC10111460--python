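"""Typed error hierarchy used across the package."""


class MRError(Exception):
    """Base class for all package errors."""


class FormatError(MRError):
    """Malformed input file (missing column, bad header, unparsable value)."""


class ValidationError(MRError):
    """Value violates a data-model invariant."""


class EmptyInputError(MRError):
    """An operation received no usable records."""


class EmptyInstrumentError(EmptyInputError):
    """No SNP passed the instrument-selection threshold."""


class HarmonizationError(MRError):
    """Allele harmonization retained zero SNPs."""

    def __init__(self, message, action_counts=None):
        super().__init__(message)
        self.action_counts = dict(action_counts or {})


class InsufficientInstrumentsError(MRError):
    """Fewer SNPs than the estimator requires."""


class DegenerateInstrumentError(MRError):
    """All-zero (or single zero where a ratio is needed) exposure effects."""


class SingularDesignError(MRError):
    """Rank-deficient regression design."""


class UnderdeterminedError(SingularDesignError):
    """More regression parameters than instruments."""


class DomainError(MRError):
    """Numeric argument outside the mathematical domain of a formula."""


class UnitError(MRError):
    """Operation applied on the wrong outcome scale (e.g. OR for a continuous trait)."""
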