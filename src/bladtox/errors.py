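"""Exception hierarchy shared across the package."""


class BladtoxError(Exception):
    """Base class for all package-specific errors."""


class MalformedDVHError(BladtoxError, ValueError):
    """A dose-volume histogram violates a structural invariant."""


class CohortValidationError(BladtoxError, ValueError):
    """Cohort-level input data are inconsistent or out of range."""


class InsufficientDataError(BladtoxError, ValueError):
    """Too few observations or grid points to carry out the operation."""


class DegenerateOutcomeError(BladtoxError, ValueError):
    """Only one outcome class is present; the model is not identifiable."""


class CollinearPredictorError(BladtoxError, ValueError):
    """The predictor is constant (or otherwise collinear with the intercept)."""


class NonInvertibleModelError(BladtoxError, ValueError):
    """A risk model with zero slope cannot be inverted for a dose-volume threshold."""


class BootstrapInstabilityError(BladtoxError, RuntimeError):
    """Too many bootstrap resamples were degenerate to trust the distribution."""


class PipelineStageError(BladtoxError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
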