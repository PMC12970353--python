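"""Exception hierarchy shared across the client/server stack."""


class BedcryptError(Exception):
    """Base class for all bedcrypt errors."""


class ParameterError(BedcryptError):
    """Invalid or unsupported HE parameters."""


class CapacityError(BedcryptError):
    """A plaintext value does not fit below the plaintext modulus."""


class AddressingError(BedcryptError):
    """Chunk id, slot offset, or logical coordinate out of range."""


class CorruptionError(BedcryptError):
    """Ciphertext can no longer be decrypted reliably (noise budget exhausted
    or the mask contract was violated)."""


class KeyError_(BedcryptError):
    """Missing or mismatched key material."""


class StoreError(BedcryptError):
    """Encrypted database store is incomplete or inconsistent."""


class StalePlanError(BedcryptError):
    """Query plan was compiled against a different database epoch."""


class ProtocolError(BedcryptError):
    """Malformed request/response or scalar stream mismatch."""


class QuerySpecError(BedcryptError):
    """Unsupported operation/mode combination."""


class PlanSizeError(BedcryptError):
    """Compiled plan exceeds the configured read cap."""


class BedParseError(BedcryptError):
    """BED or genome file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(BedcryptError):
    """Invalid synthetic-data configuration."""
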