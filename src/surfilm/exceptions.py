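"""Exception hierarchy for surfilm."""


class SurfilmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SurfilmError, ValueError):
    """Non-physical or malformed input (negative thickness, bad units, ...)."""


class DomainError(SurfilmError, ValueError):
    """Input outside a model's domain of validity (e.g. BET divergence)."""


class ConvergenceError(SurfilmError, RuntimeError):
    """A fit failed to converge; carries diagnostics where possible."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FeatureNotFoundError(SurfilmError, RuntimeError):
    """A required scan feature (TIR shoulder, resonance dip) is absent."""
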