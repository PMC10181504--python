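"""Exception types shared across the package."""


class StrideKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StrideKitError, ValueError):
    """A tunable or argument is outside its valid range."""


class InvalidInputError(StrideKitError, ValueError):
    """Input data violates an operation's precondition."""
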