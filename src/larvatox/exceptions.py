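"""Exception and warning types shared across the package."""


class LarvatoxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LarvatoxError):
    """A simulation or run configuration is invalid."""


class ValidationError(LarvatoxError):
    """Input data violate a documented contract."""


class MalformedTraceError(ValidationError):
    """A locomotion trace does not match its photoperiod schedule."""


class DegenerateDataError(LarvatoxError):
    """The data admit no meaningful test (zero margin, single group, ...)."""


class StageError(LarvatoxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class InsufficientDataWarning(UserWarning):
    """Too few observations for a rule/test; a safe default was returned."""


class LowExpectedCountWarning(UserWarning):
    """Chi-square expected cell below 5; the test was still computed."""


class DegenerateRatioWarning(UserWarning):
    """Light:dark ratio undefined (zero dark movement); treated as non-responder."""
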