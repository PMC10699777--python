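"""Exception hierarchy for the pipeline.

Every error a caller may want to catch selectively gets its own class;
all inherit from :class:`N2OPulseError` so ``except N2OPulseError`` is a
safe catch-all at the CLI boundary.
"""


class N2OPulseError(Exception):
    """Base class for all package errors."""


class ConfigError(N2OPulseError):
    """A run-configuration invariant is violated."""


class FormatError(N2OPulseError):
    """An input table does not match the expected schema."""


class DataError(N2OPulseError):
    """Input values are structurally valid but internally inconsistent."""


class DegenerateDesignError(N2OPulseError):
    """A regression design matrix is rank deficient or has no spread."""


class InsufficientDataError(N2OPulseError):
    """Too few observations to perform the requested computation."""


class MissingChannelError(N2OPulseError):
    """A required measurement stream (e.g. the delta channel) is absent."""


class CurveFailureError(N2OPulseError):
    """A qPCR standard curve is unusable (e.g. non-negative slope)."""
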