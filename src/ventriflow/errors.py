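"""Exception hierarchy shared across the pipeline.

Parameter errors signal invalid configuration before any data is touched;
data errors signal inputs that parse but cannot be analyzed; format errors
signal files that cannot be parsed at all. The CLI maps all of these to a
nonzero exit distinct from click's usage-error exit code.
"""


class VentriflowError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(VentriflowError, ValueError):
    """A configuration or simulation parameter violates an invariant."""


class DataError(VentriflowError, ValueError):
    """Input data is structurally valid but unusable for the requested analysis."""


class FormatError(DataError):
    """A file could not be interpreted under the declared dialect."""


class InsufficientBeatsError(DataError):
    """Fewer beats were detected than the requested summary needs."""


class UndefinedBaselineError(DataError):
    """A pre-drug baseline metric is zero, so a ratio to it is undefined."""


class DegenerateBeatError(DataError):
    """A beat interval carries no motion signal; callers typically skip it."""
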