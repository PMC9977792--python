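"""Exception hierarchy. Everything raised on bad data derives from Tc1ScoutError."""


class Tc1ScoutError(Exception):
    """Base class for all package errors."""


class FormatError(Tc1ScoutError):
    """Malformed input file (FASTA/GFF/TSV)."""


class AlphabetError(Tc1ScoutError):
    """Sequence contains characters outside the allowed alphabet."""


class ValidationError(Tc1ScoutError):
    """A domain-type invariant was violated."""


class SpecError(Tc1ScoutError):
    """Inconsistent synthetic-element specification."""


class PlacementError(Tc1ScoutError):
    """Not enough room (or target sites) to place planted features."""


class LayoutError(Tc1ScoutError):
    """Element segments do not assemble into a consistent five-part layout."""


class TranslationError(Tc1ScoutError):
    """Nucleotide sequence is not a translatable ORF."""


class InsufficientFlankError(Tc1ScoutError):
    """Element too close to a sequence edge for excision-site checks."""


class AmbiguousBoundaryError(Tc1ScoutError):
    """Homolog groups disagree on the inserted segment beyond tolerance."""


class UndefinedCorrelationError(Tc1ScoutError):
    """Pearson correlation undefined (zero-variance vector)."""
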