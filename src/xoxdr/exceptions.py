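"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`XoxdrError`
so callers can catch one base class; the mixin builtins (``ValueError`` /
``IOError``) keep duck-typed callers working.
"""


class XoxdrError(Exception):
    """Base class for all errors raised by xoxdr."""


class LoadError(XoxdrError, ValueError):
    """A data file could not be loaded (missing, malformed, or non-finite)."""


class ParseError(XoxdrError, ValueError):
    """A serialized model or report is structurally invalid."""


class DimensionError(XoxdrError, ValueError):
    """Incompatible shapes or an out-of-range target dimension."""


class DegenerateDataError(XoxdrError, ValueError):
    """The requested estimate is undefined for this data (e.g. identical
    class locations, zero cross-covariance)."""
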