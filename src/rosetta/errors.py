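"""Exception hierarchy.

Every failure mode of the pipeline raises a subclass of :class:`RosettaError`
so callers (CLI, benchmark loops) can distinguish "the method cannot be
applied to this input" from programming errors.
"""


class RosettaError(Exception):
    """Base class for all pipeline errors."""


class PoolValidationError(RosettaError):
    """A dataset pool violates its invariants (duplicate subjects, unknown columns...)."""


class CorrelationError(RosettaError):
    """A pairwise correlation cannot be computed (too few joint observations, zero variance)."""


class ConvergenceError(RosettaError):
    """An iterative routine (PSD projection, factor extraction, rotation) failed to converge."""


class ConditioningError(RosettaError):
    """The composite correlation matrix is too ill-conditioned / structure-free to factor."""


class ExtractionError(RosettaError):
    """Factor extraction is impossible (insufficient common variance, bad k)."""


class SingularMatrixError(RosettaError):
    """A correlation (sub)matrix required for score weights is numerically singular."""


class ScoringError(RosettaError):
    """A subject cannot be scored (no observed measures)."""


class StageError(RosettaError):
    """Wraps an error raised inside a named stage of the harmonization pipeline."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
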