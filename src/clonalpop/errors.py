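"""Exception hierarchy.

Validation failures (bad files, bad coordinates) and statistical
degeneracies (undefined test statistics) are kept distinct so callers can
tell "fix your input" apart from "this quantity does not exist here".
"""


class ClonalPopError(Exception):
    """Base class for all package errors."""


class FastaFormatError(ClonalPopError):
    """Malformed or empty FASTA input."""


class AlignmentLengthError(ClonalPopError):
    """Sequences in an alignment do not share a common length."""


class DuplicateIdError(ClonalPopError):
    """Sequence identifiers are not unique."""


class AlphabetError(ClonalPopError):
    """Sequence contains characters outside {A,C,G,T,N,-}."""


class AnnotationError(ClonalPopError):
    """Invalid feature table (bad kind, CDS length, overlap...)."""


class CoordinateError(ClonalPopError):
    """Position outside the reference or start > end."""


class ConsistencyError(ClonalPopError):
    """Stated reference allele disagrees with the reference sequence."""


class DegeneracyError(ClonalPopError):
    """Codon unsuitable for degeneracy computation (ambiguous base)."""


class StopCodonError(DegeneracyError):
    """Stop codons are excluded from degeneracy accounting."""


class InputError(ClonalPopError):
    """Malformed in-memory input (empty CDS set, alt_reads > coverage...)."""


class SerializationError(ClonalPopError):
    """Tree cannot be written (e.g. unlabeled leaf)."""


class SiteCapacityError(ClonalPopError):
    """Locus too short for infinite-sites mutation placement."""


class CapacityError(ClonalPopError):
    """Not enough candidate sites to plant the requested variants."""


class UndefinedStatisticError(ClonalPopError):
    """The requested statistic is undefined for this input (e.g. S = 0).

    Carries a machine-readable ``reason`` so summaries can report *why*
    instead of silently propagating NaN.
    """

    def __init__(self, statistic: str, reason: str):
        self.statistic = statistic
        self.reason = reason
        super().__init__(f"{statistic} undefined: {reason}")
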