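"""Exception hierarchy shared by all pipeline stages."""


class LipidraftError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(LipidraftError):
    """Input violates a documented invariant (bad value, duplicate key, ...)."""


class ParseError(LipidraftError):
    """A file does not follow its documented dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigurationError(LipidraftError):
    """A required configuration entry is missing or inconsistent."""


class QuantificationError(LipidraftError):
    """Quantification is impossible for a sample/subclass (e.g. zero IS area)."""


class StageError(LipidraftError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
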