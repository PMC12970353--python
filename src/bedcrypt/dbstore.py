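"""Global-vector layout, chunking, secret permutation, and encryption.

Per chromosome the four signal arrays are concatenated (fixed segment order
S1..S4) into one logical global vector; chromosome vectors are concatenated
in layout order.  The combined vector is split into ``chunk_size`` pieces
(last chunk zero-padded), chunk order is permuted with a client-secret
Fisher-Yates shuffle, and each permuted chunk is encrypted as one ciphertext.
The manifest plus permutation map (client-side only) translate any
(segment, chromosome, coordinate) into a (physical chunk id, slot offset)
selector; the server sees neither the manifest nor the permutation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AddressingError, CapacityError, StoreError
from .he import CipherChunk, HEBackend, HEParams, KeyMaterial
from .signals import SEGMENT_ORDER, SignalArrays


@dataclass
class LayoutManifest:
    chunk_size: int
    epoch: int
    params_fingerprint: str
    #: (chrom, segment) -> (global offset, length)
    segments: dict[tuple[str, str], tuple[int, int]]
    total_length: int

    @property
    def chunk_count(self) -> int:
        return -(-self.total_length // self.chunk_size)

    @property
    def padding(self) -> int:
        return self.chunk_count * self.chunk_size - self.total_length

    def global_index(self, segment: str, chrom: str, coordinate: int) -> int:
        key = (chrom, segment)
        if key not in self.segments:
            raise AddressingError(f"no segment {segment} for chromosome {chrom}")
        offset, length = self.segments[key]
        if not 0 <= coordinate < length:
            raise AddressingError(
                f"coordinate {coordinate} out of range [0, {length}) for "
                f"{segment}@{chrom}")
        return offset + coordinate

    def to_json(self) -> str:
        return json.dumps({
            "chunk_size": self.chunk_size,
            "epoch": self.epoch,
            "params_fingerprint": self.params_fingerprint,
            "segments": [[c, s, o, l] for (c, s), (o, l) in self.segments.items()],
            "total_length": self.total_length,
        })

    @classmethod
    def from_json(cls, text: str) -> "LayoutManifest":
        d = json.loads(text)
        return cls(d["chunk_size"], d["epoch"], d["params_fingerprint"],
                   {(c, s): (o, l) for c, s, o, l in d["segments"]},
                   d["total_length"])


@dataclass
class PermutationMap:
    """Client-secret bijection: logical chunk index -> physical chunk id."""

    epoch: int
    pi: list[int]
    seed_ref: str = "local"

    def __post_init__(self):
        if sorted(self.pi) != list(range(len(self.pi))):
            raise ValueError("pi is not a bijection over chunk indices")

    def physical(self, logical: int) -> int:
        return self.pi[logical]

    def inverse(self) -> list[int]:
        inv = [0] * len(self.pi)
        for k, p in enumerate(self.pi):
            inv[p] = k
        return inv

    def to_json(self) -> str:
        return json.dumps({"epoch": self.epoch, "pi": self.pi})

    @classmethod
    def from_json(cls, text: str) -> "PermutationMap":
        d = json.loads(text)
        return cls(d["epoch"], d["pi"])


@dataclass(frozen=True)
class Selector:
    """Server-visible address of one requested scalar."""

    physical_chunk_id: int
    slot_offset: int
    ordinal: int


@dataclass
class EncryptedDB:
    """Ciphertext chunks indexed by physical chunk id (dense 0..count-1)."""

    chunks: list[CipherChunk]
    params_fingerprint: str
    epoch: int
    backend_tag: str
    chunk_size: int

    @property
    def chunk_count(self) -> int:
        return len(self.chunks)


def concat_and_chunk(signals: SignalArrays, chunk_size: int,
                     plain_modulus: int | None = None,
                     ) -> tuple[list[np.ndarray], LayoutManifest]:
    """Concatenate segments into the global vector and cut into chunks."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    segments: dict[tuple[str, str], tuple[int, int]] = {}
    parts: list[np.ndarray] = []
    offset = 0
    for chrom in signals.layout.chroms:
        for seg in SEGMENT_ORDER:
            arr = signals.segment(seg, chrom)
            if plain_modulus is not None and arr.size and int(arr.max()) >= plain_modulus:
                raise CapacityError(
                    f"signal value {int(arr.max())} on chromosome {chrom} "
                    f"({seg}) exceeds plaintext modulus {plain_modulus}; "
                    f"chromosome too long for these HE parameters")
            segments[(chrom, seg)] = (offset, len(arr))
            parts.append(arr)
            offset += len(arr)
    total = offset
    flat = np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)
    count = -(-total // chunk_size)
    padded = np.zeros(count * chunk_size, dtype=np.int64)
    padded[:total] = flat
    chunks = [padded[i * chunk_size:(i + 1) * chunk_size].copy()
              for i in range(count)]
    manifest = LayoutManifest(chunk_size, 0, "", segments, total)
    return chunks, manifest


def permute_chunks(chunks: list[np.ndarray], secret_seed: int,
                   epoch: int = 0) -> tuple[list[np.ndarray], PermutationMap]:
    """Fisher-Yates shuffle of chunk order; contents untouched."""
    n = len(chunks)
    order = list(range(n))  # physical position -> logical index
    rng = random.Random(secret_seed)
    for i in range(n - 1, 0, -1):
        j = rng.randrange(i + 1)
        order[i], order[j] = order[j], order[i]
    pi = [0] * n
    for phys, logical in enumerate(order):
        pi[logical] = phys
    permuted = [chunks[logical] for logical in order]
    return permuted, PermutationMap(epoch, pi)


def encrypt_database(permuted_chunks: list[np.ndarray], keys: KeyMaterial,
                     backend: HEBackend, epoch: int = 0,
                     chunk_size: int | None = None) -> EncryptedDB:
    """One ciphertext per chunk.  Chunks smaller than the slot batch (toy
    layouts) are zero-padded up to ``slot_count``; selectors only ever
    address offsets below ``chunk_size``."""
    slot_count = keys.params.slot_count
    chunk_size = chunk_size or (len(permuted_chunks[0]) if permuted_chunks
                                else slot_count)
    if chunk_size > slot_count:
        raise CapacityError(
            f"chunk_size {chunk_size} exceeds slot batch {slot_count}")
    enc = []
    for c in permuted_chunks:
        if len(c) < slot_count:
            padded = np.zeros(slot_count, dtype=np.int64)
            padded[:len(c)] = c
            c = padded
        enc.append(backend.encrypt_chunk(c, keys))
    return EncryptedDB(enc, keys.params.fingerprint(), epoch, backend.tag,
                       chunk_size)


def build_database(signals: SignalArrays, keys: KeyMaterial, backend: HEBackend,
                   secret_seed: int, epoch: int = 0,
                   chunk_size: int | None = None,
                   ) -> tuple[EncryptedDB, LayoutManifest, PermutationMap]:
    """One-shot: chunk, permute, encrypt."""
    chunk_size = chunk_size or keys.params.slot_count
    chunks, manifest = concat_and_chunk(signals, chunk_size,
                                        keys.params.plain_modulus)
    permuted, perm = permute_chunks(chunks, secret_seed, epoch)
    manifest.epoch = epoch
    manifest.params_fingerprint = keys.params.fingerprint()
    db = encrypt_database(permuted, keys, backend, epoch, chunk_size)
    return db, manifest, perm


def refresh_database(signals: SignalArrays, keys: KeyMaterial, backend: HEBackend,
                     new_seed: int, old_epoch: int,
                     chunk_size: int | None = None,
                     ) -> tuple[EncryptedDB, LayoutManifest, PermutationMap]:
    """Re-randomize the chunk permutation and re-encrypt under a new epoch.

    All selectors compiled against the old epoch become invalid: the server
    rejects them with a stale-plan error on epoch mismatch.
    """
    return build_database(signals, keys, backend, new_seed,
                          epoch=old_epoch + 1, chunk_size=chunk_size)


def logical_to_selector(manifest: LayoutManifest, perm: PermutationMap,
                        segment: str, chrom: str, coordinate: int,
                        ordinal: int) -> Selector:
    gidx = manifest.global_index(segment, chrom, coordinate)
    logical_chunk, slot = divmod(gidx, manifest.chunk_size)
    return Selector(perm.physical(logical_chunk), slot, ordinal)


# ---------------------------------------------------------------- store I/O

_PARAMS_FILE = "params.json"


def save_store(db: EncryptedDB, params: HEParams, path: str | Path):
    """Server-side store: numbered ciphertext blobs + a public params file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, chunk in enumerate(db.chunks):
        (path / f"chunk_{i:05d}.bin").write_bytes(chunk.to_bytes())
    (path / _PARAMS_FILE).write_text(json.dumps({
        "fingerprint": db.params_fingerprint,
        "epoch": db.epoch,
        "chunk_count": db.chunk_count,
        "backend": db.backend_tag,
        "chunk_size": db.chunk_size,
        "poly_degree": params.poly_degree,
        "plain_modulus_bits": params.plain_modulus_bits,
        "security_bits": params.security_bits,
        "coeff_modulus_bits": list(params.coeff_modulus_bits),
        "special_count": params.special_count,
    }))


def read_store_meta(path: str | Path) -> dict:
    meta_path = Path(path) / _PARAMS_FILE
    if not meta_path.exists():
        raise StoreError(f"missing {_PARAMS_FILE} in {path}")
    return json.loads(meta_path.read_text())
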