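"""Exception hierarchy for the ptmplex pipeline.

Every error raised by this package derives from :class:`PtmplexError`, so
callers can catch pipeline failures without masking programming errors.
"""


class PtmplexError(Exception):
    """Base class for all ptmplex errors."""


class FormatError(PtmplexError):
    """A file does not conform to its declared dialect (missing column, bad line)."""


class ValidationError(PtmplexError):
    """Input content violates an invariant (duplicate channels, bad ranges)."""


class StateError(PtmplexError):
    """An operation was applied to a matrix in the wrong processing state."""


class MappingError(PtmplexError):
    """A peptide or residue does not map onto the reference sequence/structure."""


class ConfigurationError(PtmplexError):
    """A required configuration entry is missing or inconsistent."""


class UndefinedResultError(PtmplexError):
    """The requested quantity is undefined for the given input (e.g. empty table)."""
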