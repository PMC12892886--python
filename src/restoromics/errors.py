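"""Typed error hierarchy shared by all pipeline stages."""


class RestoromicsError(Exception):
    """Base class for all package errors."""


class FormatError(RestoromicsError):
    """A file does not follow the documented dialect (bad header, bad shape)."""


class ValidationError(RestoromicsError):
    """Content-level violation: bad characters, negative values, bad ranges."""


class SchemaError(RestoromicsError):
    """Table columns and sample sheet disagree."""


class ConfigError(RestoromicsError):
    """A run/simulation configuration is internally inconsistent."""


class StateError(RestoromicsError):
    """A matrix arrived at a stage in the wrong normalization state."""


class StageError(RestoromicsError):
    """Wraps a failure inside the end-to-end pipeline with its stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
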