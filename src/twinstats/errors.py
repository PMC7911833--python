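"""Exception hierarchy."""


class TwinstatsError(Exception):
    """Base class for all twinstats errors."""


class ValidationError(TwinstatsError):
    """Malformed input data or configuration."""


class ConvergenceError(TwinstatsError):
    """An iterative fit failed to converge within its iteration budget."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SeparationError(ConvergenceError):
    """Complete or quasi-complete separation in a logistic fit.

    The MLE lies at infinity; no finite odds ratio exists. Following the
    design of the analysis this is flagged rather than penalised.
    """


class PipelineError(TwinstatsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
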