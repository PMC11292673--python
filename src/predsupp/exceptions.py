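"""Package-wide exception and warning types."""


class PredsuppError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PredsuppError, ValueError):
    """Inconsistent design or pipeline configuration."""


class TimingError(PredsuppError, ValueError):
    """Impossible event timing (negative gaps, events past run end)."""


class DegenerateDesignError(PredsuppError, ValueError):
    """Design matrix is rank deficient or has empty condition columns."""


class DataError(PredsuppError, ValueError):
    """Malformed or non-finite input data."""


class AlignmentError(PredsuppError, ValueError):
    """Observation sets that must match do not (count or ordering)."""


class InitializationError(PredsuppError, RuntimeError):
    """Sampler log density non-finite at the initialization point."""


class UnsupportedStructureError(PredsuppError, ValueError):
    """Path model graph is not a simple chain."""


class ConvergenceWarning(UserWarning):
    """MCMC convergence diagnostics exceeded their threshold."""


class DegenerateDrawsWarning(UserWarning):
    """Posterior draws are degenerate (constant, or undefined diagnostics)."""
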