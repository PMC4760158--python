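"""Exception hierarchy shared across the pipeline."""


class PlanktteError(Exception):
    """Base class for all package errors."""


class ValidationError(PlanktteError, ValueError):
    """Input data violates a precondition (non-positive axis, bad weight, ...)."""


class ConfigurationError(PlanktteError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class DegenerateSampleError(PlanktteError, ValueError):
    """A size sample is too degenerate for density estimation
    (fewer than two points, or all values identical without a fixed bandwidth)."""
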