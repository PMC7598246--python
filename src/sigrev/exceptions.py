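"""Exception hierarchy.

Every validation failure raises a subclass of :class:`SigrevError` so callers
can catch pipeline errors without swallowing programming errors.
"""


class SigrevError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SigrevError, ValueError):
    """A configuration value is outside its documented domain."""


class WrongScaleError(SigrevError, ValueError):
    """An operation received a matrix on the wrong scale (log2 vs count)."""


class MissingGeneError(SigrevError, KeyError):
    """A query gene is absent from the reference universe."""


class InvalidSignatureError(SigrevError, ValueError):
    """A gene signature violates its invariants (empty or overlapping sets)."""


class DegenerateInputError(SigrevError, ValueError):
    """Input is structurally valid but statistically degenerate."""


class FormatError(SigrevError, ValueError):
    """A file does not conform to its declared format."""
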