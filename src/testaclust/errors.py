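"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An argument violates an operation's documented precondition."""


class EmptyPatchError(InvalidInputError):
    """Patch extraction found no foreground component to crop."""


class ConfigurationError(InvalidInputError):
    """A pipeline or battery configuration is incomplete or inconsistent."""
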