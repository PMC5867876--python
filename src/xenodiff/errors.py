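"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`XenodiffError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
to stay idiomatic for input-validation failures.
"""


class XenodiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XenodiffError, ValueError):
    """A configuration value is missing or refers to something absent."""


class FormatError(XenodiffError, ValueError):
    """An input file violates the expected tabular format."""


class ParameterError(XenodiffError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateResultError(XenodiffError, ValueError):
    """An operation would return an empty or single-class result."""


class DegenerateLabelError(DegenerateResultError):
    """Labels carry fewer than two classes where two are required."""


class LogicError(XenodiffError):
    """An internal consistency check failed (caller-side contract breach)."""
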