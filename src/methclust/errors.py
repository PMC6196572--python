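"""Exception types shared across the package."""


class MethclustError(Exception):
    """Base class for all package errors."""


class ParseError(MethclustError):
    """A file could not be parsed; message carries line/coordinate context."""


class ValidationError(MethclustError):
    """Parsed data violate a container invariant."""


class ContractError(MethclustError):
    """An operation was invoked outside its stated precondition."""
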