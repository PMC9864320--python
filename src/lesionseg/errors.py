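"""Exception types shared across the package."""


class LesionSegError(Exception):
    """Base class for package-specific errors."""


class ValidationError(LesionSegError, ValueError):
    """Raised when inputs violate a documented contract."""


class InputError(LesionSegError, OSError):
    """Raised when a file cannot be read or written."""


class NumericError(LesionSegError, ArithmeticError):
    """Raised when a computation produces non-finite values."""
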