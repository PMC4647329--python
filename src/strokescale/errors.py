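"""Exception hierarchy shared across the package."""


class StrokeScaleError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(StrokeScaleError, ValueError):
    """A patient record or cohort violates a domain invariant."""


class CohortLoadError(StrokeScaleError, ValueError):
    """A cohort file could not be parsed into valid records."""


class ScaleError(StrokeScaleError, ValueError):
    """A scale definition is malformed."""


class ScoringError(StrokeScaleError, ValueError):
    """A record lacks a feature an item's categorizer needs."""


class ScreeningError(StrokeScaleError, ValueError):
    """A screening statistic is undefined for the given input."""


class FitError(StrokeScaleError, ValueError):
    """A regression fit failed (rank deficiency, non-convergence)."""


class SeparationError(FitError):
    """Perfect separation detected: the likelihood is monotone in some beta."""


class EvaluationError(StrokeScaleError, ValueError):
    """ROC / confusion-matrix evaluation is undefined for the input."""


class PipelineError(StrokeScaleError, RuntimeError):
    """An end-to-end pipeline stage failed."""
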