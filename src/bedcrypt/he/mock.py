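"""Plaintext mock backend with a calibrated noise ledger.

Same slot semantics as the lattice backend but payloads are plain vectors,
so the whole pipeline runs fast and without any hard dependency.  The noise
ledger mirrors the real extraction circuit at reference parameters: a fresh
chunk starts at 136 bits, a logical rotation costs 3, a plaintext mask costs
35 (136 -> 133 -> 98), clamped at zero.
"""

from __future__ import annotations

import struct

import numpy as np

from ..errors import CorruptionError, KeyError_, ParameterError
from .base import CipherChunk, HEBackend, KeyMaterial
from .params import HEParams

FRESH_BUDGET = 136
ROTATION_COST = 3
MASK_COST = 35


class MockBackend(HEBackend):
    tag = "mock"

    def keygen(self, params: HEParams, seed: int | None = None) -> KeyMaterial:
        # deterministic stub: the key id doubles as the "secret"
        key_id = 0 if seed is None else int(seed)
        return KeyMaterial(params, {"key_id": key_id}, {"key_id": key_id})

    def encrypt_chunk(self, values, keys: KeyMaterial) -> CipherChunk:
        values = self._check_values(values, keys.params)
        self.counter.encrypts += 1
        return CipherChunk(self.tag, keys.params.fingerprint(), values.copy(),
                           {"budget": FRESH_BUDGET,
                            "key_id": keys.public_part["key_id"]})

    def bring_to_front(self, chunk: CipherChunk, offset: int,
                       keys: KeyMaterial) -> CipherChunk:
        offset = self._check_offset(offset, keys.params)
        self._check_chunk(chunk, keys.params)
        v = chunk.payload
        half = len(v) // 2
        row0, row1 = v[:half], v[half:]
        self.counter.rotations += 1
        if offset >= half:
            row0, row1 = row1, row0
            offset -= half
            self.counter.galois += 1  # row swap
        # one Galois op per set bit of the step, as in the real backend
        self.counter.galois += bin(offset).count("1")
        out = np.concatenate([np.roll(row0, -offset), np.roll(row1, -offset)])
        meta = dict(chunk.meta)
        meta["budget"] = max(0, meta.get("budget", FRESH_BUDGET) - ROTATION_COST)
        return CipherChunk(self.tag, chunk.fingerprint, out, meta)

    def mask_front(self, chunk: CipherChunk, keys: KeyMaterial) -> CipherChunk:
        self._check_chunk(chunk, keys.params)
        out = np.zeros_like(chunk.payload)
        out[0] = chunk.payload[0]
        meta = dict(chunk.meta)
        meta["budget"] = max(0, meta.get("budget", FRESH_BUDGET) - MASK_COST)
        self.counter.masks += 1
        return CipherChunk(self.tag, chunk.fingerprint, out, meta)

    def decrypt_chunk(self, chunk: CipherChunk, keys: KeyMaterial) -> np.ndarray:
        if not keys.has_secret:
            raise KeyError_("decryption requires the secret key")
        self._check_chunk(chunk, keys.params)
        if chunk.meta.get("budget", FRESH_BUDGET) <= 0:
            raise CorruptionError("noise budget exhausted")
        self.counter.decrypts += 1
        if keys.secret_part["key_id"] != chunk.meta.get("key_id"):
            # wrong key: deterministic garbage, mirroring real-backend behaviour
            t = keys.params.plain_modulus
            scramble = np.random.default_rng(
                keys.secret_part["key_id"] ^ 0x5EED).integers(
                    1, t, len(chunk.payload), dtype=np.int64)
            return (chunk.payload + scramble) % t
        return chunk.payload.copy()

    def noise_budget(self, chunk: CipherChunk, keys: KeyMaterial) -> int:
        self._check_chunk(chunk, keys.params)
        return int(chunk.meta.get("budget", FRESH_BUDGET))

    def _serialize_payload(self, payload) -> bytes:
        return struct.pack("<I", len(payload)) + payload.astype(np.int64).tobytes()

    def _deserialize_payload(self, blob: bytes, params: HEParams | None):
        (n,) = struct.unpack("<I", blob[:4])
        v = np.frombuffer(blob[4:], dtype=np.int64)
        if v.size != n:
            raise ParameterError("truncated mock payload")
        return v.copy()

    def _check_chunk(self, chunk: CipherChunk, params: HEParams):
        if chunk.backend != self.tag:
            raise ParameterError(
                f"chunk belongs to backend '{chunk.backend}', not '{self.tag}'")
        if chunk.fingerprint != params.fingerprint():
            raise ParameterError("chunk/params fingerprint mismatch")
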