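"""Exception hierarchy for ccmorph.

Every user-facing failure mode raises a distinct subclass of
:class:`CCMorphError` so callers (and the CLI) can map failures to exit
diagnostics without string matching.
"""


class CCMorphError(Exception):
    """Base class for all ccmorph errors."""


class MaskReadError(CCMorphError):
    """A mask file could not be read."""


class MissingFileError(MaskReadError, FileNotFoundError):
    """The requested input file does not exist."""


class DimensionError(MaskReadError):
    """Input image has more than two non-singleton dimensions."""


class EmptyMaskError(CCMorphError):
    """A mask contains no foreground pixels."""


class ZeroExtentRectangleError(CCMorphError):
    """The foreground is degenerate (spans a single row or column), so no
    two-dimensional bounding rectangle exists."""


class ValidationError(CCMorphError):
    """A record, table or configuration failed validation."""


class InfeasibleShapeError(CCMorphError):
    """Requested synthetic geometry cannot be realised (e.g. a sub-region
    demands a thickness exceeding half the arch height)."""


class RegistrationError(CCMorphError):
    """Registration or template construction failed (grid mismatch,
    divergence)."""
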