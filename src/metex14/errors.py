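"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class UndefinedCorrelationError(ValidationError):
    """Pearson correlation is undefined (fewer than 3 pairs or zero variance)."""


class MissingPredictorError(ValidationError):
    """A predictor annotation required for the consensus vote is absent."""
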