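"""Exception hierarchy for the pipeline."""


class PsykernelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PsykernelError):
    """Invalid scene or observer configuration."""


class SchedulingError(PsykernelError):
    """No eligible item could be found for a displacement draw."""


class PreprocessingError(PsykernelError):
    """Gaze trace unusable (e.g. entirely invalid)."""


class InsufficientDataError(PsykernelError):
    """Too few samples/trials for the requested computation."""


class DegenerateKernelError(PsykernelError):
    """Density difference or fitted covariance is degenerate."""
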