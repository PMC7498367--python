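"""Shared exception types."""


class ConfigurationError(ValueError):
    """An invalid tunable or a template incompatible with the configured axes."""


class SchemaError(ValueError):
    """A table violated the on-disk schema (missing strips, bad vocabularies, ...)."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the offender."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
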