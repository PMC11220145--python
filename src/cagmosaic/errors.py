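"""Exception hierarchy for the cagmosaic pipeline."""


class CagMosaicError(Exception):
    """Base class for all cagmosaic errors."""


class InsufficientReadsError(CagMosaicError):
    """Too few passing reads to genotype a sample."""


class AmbiguousGenotypeError(CagMosaicError):
    """More than two allele peaks survive stutter-aware peak calling."""


class UndefinedRatioError(CagMosaicError):
    """No reads at the inherited repeat length; the expansion ratio is undefined."""


class BaselineMismatchError(CagMosaicError):
    """Baseline model and expansion profile refer to different inherited lengths."""


class UndefinedFoldError(CagMosaicError):
    """Zero denominator frequency in a tissue fold-change comparison."""


class CollinearDesignError(CagMosaicError):
    """Rank-deficient regression design; names the collinear term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"design matrix is rank deficient: column {term!r} is collinear/constant")


class SchemaError(CagMosaicError):
    """An input table violates the expected schema."""
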