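"""Exception hierarchy.

Every error raised by propseq derives from :class:`PropseqError`, so callers
(and the CLI) can catch one type and map it to a diagnostic.
"""


class PropseqError(Exception):
    """Base class for all propseq errors."""


class AlignmentError(PropseqError):
    """Malformed alignment input (ragged rows, duplicate labels, bad characters)."""


class EncodingError(PropseqError):
    """A residue could not be mapped through a property/factor table."""


class DimensionError(PropseqError):
    """Operands have incompatible shapes or lengths."""


class DegenerateInputError(PropseqError):
    """Input is constant/empty where variation is required."""


class ConfigError(PropseqError):
    """Invalid configuration values."""
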