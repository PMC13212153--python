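"""Exception hierarchy."""


class NutrinetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NutrinetError, ValueError):
    """Invalid or contradictory configuration."""


class DomainError(NutrinetError, ValueError):
    """A quantity is outside its mathematically admissible domain."""


class DataError(NutrinetError, ValueError):
    """Required data are missing or inconsistent."""


class ValidationError(DataError):
    """Schema/invariant validation failure with an itemised report."""

    def __init__(self, items):
        self.items = list(items)
        super().__init__("validation failed:\n" + "\n".join(f"- {i}" for i in self.items))
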