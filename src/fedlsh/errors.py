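"""Exception hierarchy, categorized the way the CLI reports failures."""


class FedLshError(Exception):
    """Base class for all package errors."""

    category = "error"


class InvalidConfigError(FedLshError, ValueError):
    category = "config"


class InvalidDimensionError(InvalidConfigError):
    category = "config"


class InvalidKeyError(FedLshError, ValueError):
    category = "config"


class ParseError(FedLshError, ValueError):
    category = "parse"


class ProtocolError(FedLshError, RuntimeError):
    category = "protocol"


class VerificationFailedError(ProtocolError):
    """The cloud's claimed product failed the random-vector check."""

    category = "verification-failed"
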