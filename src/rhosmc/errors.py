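"""Exception types shared across the package."""


class RhoSMCError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RhoSMCError, ValueError):
    """An argument violates a documented precondition."""


class InvalidInputError(RhoSMCError, ValueError):
    """Malformed input data (sequences, files, configs)."""


class NumericError(RhoSMCError, ArithmeticError):
    """A numerical failure (zero likelihood, non-finite spline, ...)."""
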