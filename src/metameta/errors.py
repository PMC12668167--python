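"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: :class:`DomainError` /
:class:`ValidationError` -> 2, :class:`ConvergenceError` -> 3.
"""


class MetaMetaError(Exception):
    """Base class for all package errors."""


class DomainError(MetaMetaError, ValueError):
    """An input violates a mathematical precondition (p out of (0,1], n < 4, ...)."""


class ValidationError(MetaMetaError, ValueError):
    """A table, config or schema is malformed."""


class ConvergenceError(MetaMetaError, RuntimeError):
    """An iterative procedure failed to stabilize; carries a state dump."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = dict(state or {})
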