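"""Exception hierarchy shared across the pipeline stages."""


class PopomicsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PopomicsError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class DomainError(PopomicsError, ValueError):
    """An input is mathematically outside the operation's domain
    (e.g. zero total mapped reads, empty sequence)."""


class InputError(PopomicsError, ValueError):
    """Malformed input data (bad file record, unknown category symbol...)."""


class ConsistencyError(PopomicsError, ValueError):
    """Two inputs that must agree do not (e.g. a counted contig unknown to
    the bin assignment)."""


class DegeneracyError(PopomicsError, RuntimeError):
    """A mixture component collapsed during EM."""

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(message or f"mixture component {component} is degenerate")


class DependencyError(PopomicsError, RuntimeError):
    """A pipeline stage is missing the output of an upstream stage."""
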