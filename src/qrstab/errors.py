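"""Exception hierarchy for the QR transmission protocol."""


class QRSTError(Exception):
    """Base class for all package errors."""


class RangeError(QRSTError, ValueError):
    """A protocol field or parameter is outside its declared range."""


class FramingError(QRSTError, ValueError):
    """Raw bytes do not parse as a valid packet or token stream."""


class CapacityExceededError(QRSTError, ValueError):
    """The message body needs more subpackets than the protocol allows."""


class EmptyMessageError(QRSTError, ValueError):
    """A zero-length message body cannot be packetized."""


class SchemaValidationError(QRSTError, ValueError):
    """A record does not conform to its schema; carries the failing path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class DeserializationError(QRSTError, ValueError):
    """A binary stream cannot be decoded under the given schema."""


class TrainingError(QRSTError, ValueError):
    """Tokenizer training received unusable input."""


class ScanError(QRSTError, ValueError):
    """A QR image could not be located or decoded."""


class ProfileError(QRSTError, ValueError):
    """Codec profile registry misuse (duplicate or malformed profile)."""
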