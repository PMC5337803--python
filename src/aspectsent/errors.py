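"""Exception types shared across the pipeline."""


class AspectSentError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AspectSentError):
    """A requested backend or option is unavailable or inconsistent."""


class FormatError(AspectSentError):
    """An input file does not conform to its declared format."""

    def __init__(self, message: str, *, line: int | None = None, source: str | None = None):
        self.line = line
        self.source = source
        prefix = ""
        if source is not None:
            prefix += f"{source}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ContractViolation(AspectSentError):
    """A caller violated a documented precondition."""


class GenerationError(AspectSentError):
    """The synthetic-corpus generator was asked for an impossible configuration."""
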