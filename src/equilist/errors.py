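"""Exception hierarchy shared across the package."""


class EquilistError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EquilistError):
    """An input file is structurally unusable (missing column, bad format)."""


class ValidationError(EquilistError):
    """A record violates a domain invariant; message itemizes each violation."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class ModelError(EquilistError):
    """The impact model hit a degenerate configuration (division by zero residual,
    contraception removing all fecund exposure)."""
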