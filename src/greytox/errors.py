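"""Exception hierarchy shared across the package."""


class GreytoxError(Exception):
    """Base class for all package errors."""


class SchemaError(GreytoxError):
    """Input file or table does not match the declared schema."""


class PanelValidationError(GreytoxError):
    """A toxicity panel violates an invariant.

    Carries the structured findings so callers can report every violation,
    not only the first.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings)
        super().__init__(f"panel validation failed: {lines}")


class ConfigError(GreytoxError):
    """Invalid analysis configuration (rho, weights, reference, ...)."""


class DegeneratePanelError(GreytoxError):
    """Every comparison value equals the reference; the grey coefficient
    is undefined (0/0) for such a panel."""


class UndefinedRateError(GreytoxError):
    """Change rate requested against a zero baseline."""
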