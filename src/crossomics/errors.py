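"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a plain failure.
"""


class CrossOmicsError(Exception):
    """Base class for package errors."""


class ConfigError(CrossOmicsError):
    """Invalid configuration (bad dimensions, missing files, malformed YAML)."""


class DataError(CrossOmicsError):
    """Invalid data values (negative counts, non-positive molecular weights...)."""


class PipelineError(CrossOmicsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
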