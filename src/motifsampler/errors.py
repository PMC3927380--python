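"""Exception hierarchy for motifsampler.

Every error raised by the package derives from :class:`MotifSamplerError`
so callers can catch pipeline failures with a single except clause.
"""


class MotifSamplerError(Exception):
    """Base class for all motifsampler errors."""


class EmptyInputError(MotifSamplerError):
    """An input (FASTA file, sequence set) contained no usable records."""


class DuplicateIdError(MotifSamplerError):
    """Two records in one sequence set share an identifier."""


class ZeroLengthRecordError(MotifSamplerError):
    """A FASTA record has an empty sequence."""


class AlphabetError(MotifSamplerError):
    """A residue outside the accepted alphabet was encountered."""


class AlignmentError(MotifSamplerError):
    """A motif alignment is inconsistent with its sequence set."""


class BackgroundError(MotifSamplerError):
    """A background composition is degenerate (zero total or negative count)."""


class SearchSpaceError(MotifSamplerError):
    """Exhaustive enumeration was requested on an intractably large instance."""
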