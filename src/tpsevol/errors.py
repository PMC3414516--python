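"""Exception hierarchy for the package."""


class TpsEvolError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(TpsEvolError):
    """Sequence contains symbols outside the expected alphabet."""


class PrematureStopError(TpsEvolError):
    """An internal (non-terminal) stop codon was found in a CDS."""


class BackTranslationError(TpsEvolError):
    """Protein row and CDS disagree in length or translation."""


class EmptyAlignmentError(TpsEvolError):
    """A masking or subsetting step removed every alignment column."""


class InvalidGeneModelError(TpsEvolError):
    """Exon/CDS intervals are malformed (overlap, bad order)."""


class UndefinedIdentityError(TpsEvolError):
    """Percent identity has a zero denominator."""


class MissingClassError(TpsEvolError):
    """A sequence id has no class label where one is required."""


class TreeDataMismatchError(TpsEvolError):
    """Tree leaves and alignment ids do not match."""


class NotNestedError(TpsEvolError):
    """Likelihood-ratio test requested on non-nested or different-data fits."""


class ConfigError(TpsEvolError):
    """Invalid or incomplete run configuration (user error)."""
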