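"""Exception hierarchy shared across the pipeline.

All user-input problems derive from :class:`ThyrosigError` so the CLI can
map them onto exit codes (validation -> 2, runtime -> 1).
"""


class ThyrosigError(Exception):
    """Base class for all package errors."""


class ValidationError(ThyrosigError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file or formula could not be parsed."""


class DomainError(ValidationError):
    """A numeric argument is outside the mathematically valid domain."""


class TrainingError(ThyrosigError, RuntimeError):
    """Model optimisation failed (non-finite loss, divergence)."""
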