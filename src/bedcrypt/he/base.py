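"""Backend-neutral types and the minimal capability interface.

Both backends expose the same five operations (encrypt, rotate-to-front,
mask, decrypt, noise budget) over :class:`CipherChunk`.  Slot layout is a
flat vector of ``slot_count`` slots organised as two batching rows of
``slot_count/2``; ``bring_to_front`` hides that layout behind a single
"move slot ``offset`` to slot 0" contract.
"""

from __future__ import annotations

import json
import struct
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..errors import AddressingError, CapacityError, ParameterError
from .params import HEParams

_MAGIC = b"BCCH"


@dataclass
class CipherChunk:
    """One ciphertext holding a fixed-size slot batch of the global vector.

    ``payload`` is backend-private state; ``to_bytes``/``from_bytes`` give the
    opaque wire form (backend tag + params fingerprint + payload blob).
    """

    backend: str
    fingerprint: str
    payload: Any
    meta: dict = field(default_factory=dict)

    def to_bytes(self) -> bytes:
        from . import get_backend
        blob = get_backend(self.backend)._serialize_payload(self.payload)
        header = json.dumps({
            "backend": self.backend,
            "fingerprint": self.fingerprint,
            "meta": self.meta,
        }).encode()
        return _MAGIC + struct.pack("<I", len(header)) + header + blob

    @classmethod
    def from_bytes(cls, raw: bytes, expected_backend: str | None = None,
                   params: HEParams | None = None) -> "CipherChunk":
        if raw[:4] != _MAGIC:
            raise ParameterError("not a serialized cipher chunk")
        (hlen,) = struct.unpack("<I", raw[4:8])
        header = json.loads(raw[8:8 + hlen].decode())
        if expected_backend is not None and header["backend"] != expected_backend:
            raise ParameterError(
                f"cross-backend deserialization rejected: chunk is "
                f"'{header['backend']}', expected '{expected_backend}'")
        if params is not None and header["fingerprint"] != params.fingerprint():
            raise ParameterError("params fingerprint mismatch")
        from . import get_backend
        payload = get_backend(header["backend"])._deserialize_payload(
            raw[8 + hlen:], params)
        return cls(header["backend"], header["fingerprint"], payload,
                   header.get("meta", {}))


@dataclass
class KeyMaterial:
    """public_part suffices for encrypt/rotate/mask; decryption needs secret_part."""

    params: HEParams
    public_part: Any
    secret_part: Any | None

    @property
    def has_secret(self) -> bool:
        return self.secret_part is not None

    def public_only(self) -> "KeyMaterial":
        return KeyMaterial(self.params, self.public_part, None)


class OpCounter:
    """Counts logical homomorphic operations; the server diffs snapshots to
    verify that the kernel is identical for every selector."""

    __slots__ = ("rotations", "galois", "masks", "encrypts", "decrypts")

    def __init__(self):
        self.reset()

    def reset(self):
        self.rotations = 0   # logical bring-to-front calls
        self.galois = 0      # primitive Galois automorphisms applied
        self.masks = 0
        self.encrypts = 0
        self.decrypts = 0

    def snapshot(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in self.__slots__}


class HEBackend(ABC):
    """Minimal BFV capability set shared by the real and mock backends."""

    tag: str

    def __init__(self):
        self.counter = OpCounter()

    # -- key management -------------------------------------------------
    @abstractmethod
    def keygen(self, params: HEParams, seed: int | None = None) -> KeyMaterial:
        ...

    # -- core ops -------------------------------------------------------
    @abstractmethod
    def encrypt_chunk(self, values: np.ndarray, keys: KeyMaterial) -> CipherChunk:
        ...

    @abstractmethod
    def bring_to_front(self, chunk: CipherChunk, offset: int,
                       keys: KeyMaterial) -> CipherChunk:
        ...

    @abstractmethod
    def mask_front(self, chunk: CipherChunk, keys: KeyMaterial) -> CipherChunk:
        ...

    @abstractmethod
    def decrypt_chunk(self, chunk: CipherChunk, keys: KeyMaterial) -> np.ndarray:
        ...

    @abstractmethod
    def noise_budget(self, chunk: CipherChunk, keys: KeyMaterial) -> int:
        ...

    # -- serialization hooks -------------------------------------------
    @abstractmethod
    def _serialize_payload(self, payload: Any) -> bytes:
        ...

    @abstractmethod
    def _deserialize_payload(self, blob: bytes, params: HEParams | None) -> Any:
        ...

    # -- shared validation ----------------------------------------------
    def _check_values(self, values: np.ndarray, params: HEParams) -> np.ndarray:
        values = np.asarray(values, dtype=np.int64)
        if values.shape != (params.slot_count,):
            raise CapacityError(
                f"expected {params.slot_count} slots, got shape {values.shape}")
        t = params.plain_modulus
        if values.min(initial=0) < 0 or values.max(initial=0) >= t:
            raise CapacityError(
                f"slot values must lie in [0, {t}); "
                f"range is [{values.min()}, {values.max()}]")
        return values

    def _check_offset(self, offset: int, params: HEParams) -> int:
        offset = int(offset)
        if not 0 <= offset < params.slot_count:
            raise AddressingError(
                f"slot offset {offset} out of range [0, {params.slot_count})")
        return offset


def rotate_slots_reference(values: np.ndarray, offset: int) -> np.ndarray:
    """Plaintext reference of the two-row bring-to-front semantics."""
    n = len(values)
    half = n // 2
    rows = [values[:half], values[half:]]
    if offset >= half:
        rows = rows[::-1]
        offset -= half
    return np.concatenate([np.roll(rows[0], -offset), np.roll(rows[1], -offset)])
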