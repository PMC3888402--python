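"""Exception hierarchy shared across the package."""


class ConflictDynError(Exception):
    """Base class for all package errors."""


class ParameterError(ConflictDynError, ValueError):
    """A parameter is non-finite, out of range, or otherwise invalid."""


class FormatError(ConflictDynError, ValueError):
    """A data file violates the expected CSV dialect or coding domain."""


class InsufficientDataError(ConflictDynError, ValueError):
    """Too few observations to carry out the requested estimate."""


class FitFailureError(ConflictDynError, RuntimeError):
    """All optimizer starts failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateInputError(ConflictDynError, ValueError):
    """Input is constant or otherwise carries no usable variation."""


class UnstableEstimateError(ConflictDynError, RuntimeError):
    """Resampling produced too many fit failures for a reliable interval."""


class PipelineError(ConflictDynError, RuntimeError):
    """A pipeline stage failed; names the stage and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
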