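"""Exception hierarchy shared across the package."""


class CppScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(CppScreenError, ValueError):
    """Invalid input data (bad tokens, malformed tables, degenerate cohorts)."""


class ConfigError(CppScreenError, ValueError):
    """Invalid configuration (band out of range, bad hyperparameter keys...)."""


class TooShortError(ValidationError):
    """Signal shorter than one analysis frame."""
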