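"""Exception hierarchy used across the pipeline."""


class FnirsgluError(Exception):
    """Base class for all package errors."""


class ConfigError(FnirsgluError):
    """Invalid configuration value or unsupported parameter combination."""


class OpticsError(ConfigError):
    """Degenerate optical model (e.g. singular extinction matrix)."""


class DataError(FnirsgluError):
    """Malformed or physically impossible input data."""


class StageError(FnirsgluError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
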