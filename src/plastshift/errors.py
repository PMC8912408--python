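"""Exception hierarchy for the pipeline."""


class PlastshiftError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PlastshiftError):
    """A file could not be parsed as the expected format."""


class RaggedAlignmentError(FormatError):
    """Aligned FASTA rows have unequal lengths."""


class ValidationError(PlastshiftError):
    """Input violates a documented precondition."""


class AmbiguityError(ValidationError):
    """Input admits more than one interpretation (e.g. multi-record file)."""


class BoundsError(ValidationError):
    """A coordinate lies outside the genome or alignment."""


class NoQuadripartiteError(PlastshiftError):
    """No inverted repeat of the required minimum length exists."""


class DegenerateStructureError(PlastshiftError):
    """The repeat pair covers the whole circle, leaving no single-copy gap."""


class AnnotationRequiredError(ValidationError):
    """Operation needs gene features but the annotation is empty."""


class ClassificationError(ValidationError):
    """A feature could not be placed in a census category."""


class SpacerUndefinedError(ValidationError):
    """A flanking gene of the requested spacer is absent."""


class PrimerAlphabetError(ValidationError):
    """Primer contains non-ACGT characters."""


class WindowTooLargeError(ValidationError):
    """A QC window exceeds the span of a genome region."""


class InsufficientTaxaError(ValidationError):
    """Too few alignment rows for the requested analysis."""


class OverlapError(ValidationError):
    """Inversion intervals overlap after merging."""


class AnchorError(ValidationError):
    """A gene anchoring a comparison window is absent."""


class TaxonMismatchError(ValidationError):
    """Taxon sets of tree and alignment (or of blocks) disagree."""


class EmptyMatrixError(PlastshiftError):
    """Masking removed every column."""


class NotInternalBranchError(ValidationError):
    """Requested branch is pendant to a leaf."""


class InfeasibleSpecError(ValidationError):
    """A synthetic-genome spec cannot be realized."""
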