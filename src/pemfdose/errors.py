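"""Exception hierarchy shared across the package."""


class PemfDoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PemfDoseError):
    """A parameter value or combination of values is physically invalid."""


class SingularPointError(PemfDoseError):
    """A field was requested at a point lying on (or too close to) the wire."""


class PlacementError(PemfDoseError):
    """Coil placement intersects the phantom or cannot be constructed."""


class SegmentationError(PemfDoseError):
    """Region growing or mask post-processing failed."""


class ConvergenceError(PemfDoseError):
    """Iterative linear solve did not reach the requested residual."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history if residual_history is not None else []


class InvariantViolation(PemfDoseError):
    """Two objects that must be congruent (grids, frequency lists) are not."""


class PipelineStageError(PemfDoseError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
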