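"""Exception types shared across the pipeline."""


class NotchDoseError(Exception):
    """Base class for package errors."""


class ConfigurationError(NotchDoseError, ValueError):
    """A configuration value is invalid or inconsistent."""


class ParseError(NotchDoseError, ValueError):
    """A text input could not be parsed; message names the file/line."""


class PipelineError(NotchDoseError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
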