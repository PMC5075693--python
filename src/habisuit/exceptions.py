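"""Exception taxonomy for the habisuit pipeline.

All habisuit errors derive from :class:`HabisuitError` so callers can catch
the package's failures with a single except clause while still
distinguishing schema problems from numerical degeneracies.
"""


class HabisuitError(Exception):
    """Base class for all habisuit errors."""


class ValidationError(HabisuitError, ValueError):
    """An input violates a documented precondition (bad value, bad label)."""


class SchemaError(ValidationError):
    """A file is structurally wrong (missing column, missing tag, bad key)."""


class AlignmentError(ValidationError):
    """Raster layers are not co-registered (shape / geotransform mismatch)."""


class DegenerateInputError(ValidationError):
    """Numerically valid input on which the requested quantity is undefined
    (all-zero contents, constant observations, zero valid cells)."""


class DomainError(ValidationError):
    """A value lies outside the mathematical domain of an operation
    (non-finite membership argument)."""


class FitError(HabisuitError, RuntimeError):
    """The curve-fitting optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
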