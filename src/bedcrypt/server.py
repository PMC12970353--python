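"""Server: hosts the encrypted chunk store and runs the blind-extraction
kernel.

The server never holds a secret key and never branches on plaintext values;
every selector triggers the identical fixed kernel
``mask_front(bring_to_front(chunk, offset))`` regardless of which query class
it serves.  Execution streams chunk by chunk with a small bounded cache, so
peak working memory is independent of database size and request length.
Errors abort the whole batch (no per-selector error stream, which would be a
value-dependent side channel).
"""

from __future__ import annotations

import json
import socket
import struct
import time
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

from .dbstore import EncryptedDB, Selector, read_store_meta
from .errors import (AddressingError, ProtocolError, StalePlanError, StoreError)
from .he import CipherChunk, HEParams, KeyMaterial, get_backend

_CHUNK_CACHE_SIZE = 4  # bounded working set: streaming contract


@dataclass
class ExtractionRequest:
    epoch: int
    selectors: list[Selector]

    def validate(self, chunk_count: int, chunk_size: int):
        if not self.selectors:
            raise ProtocolError("empty extraction request")
        for sel in self.selectors:
            if not 0 <= sel.physical_chunk_id < chunk_count:
                raise AddressingError(
                    f"chunk id {sel.physical_chunk_id} out of range "
                    f"[0, {chunk_count})")
            if not 0 <= sel.slot_offset < chunk_size:
                raise AddressingError(
                    f"slot offset {sel.slot_offset} out of range "
                    f"[0, {chunk_size})")


@dataclass
class ExtractionResponse:
    epoch: int
    results: list[tuple[int, CipherChunk]]  # (ordinal, scalar ciphertext)


class HostedDB:
    """Read-only handle over a chunk store (in-memory or on disk)."""

    def __init__(self, *, chunk_count: int, chunk_size: int, epoch: int,
                 fingerprint: str, backend_tag: str, loader,
                 public_keys: KeyMaterial):
        self.chunk_count = chunk_count
        self.chunk_size = chunk_size
        self.epoch = epoch
        self.fingerprint = fingerprint
        self.backend_tag = backend_tag
        self._loader = loader
        self._cache: OrderedDict[int, CipherChunk] = OrderedDict()
        self.keys = public_keys  # public part only
        self.last_batch_stats: dict = {}

    def chunk(self, chunk_id: int) -> CipherChunk:
        if chunk_id in self._cache:
            self._cache.move_to_end(chunk_id)
            return self._cache[chunk_id]
        chunk = self._loader(chunk_id)
        self._cache[chunk_id] = chunk
        while len(self._cache) > _CHUNK_CACHE_SIZE:
            self._cache.popitem(last=False)
        return chunk


def host_db(db: EncryptedDB, keys: KeyMaterial) -> HostedDB:
    """In-process hosting of an already built EncryptedDB."""
    if keys.has_secret:
        keys = keys.public_only()  # the server must never see secret material
    return HostedDB(chunk_count=db.chunk_count, chunk_size=db.chunk_size,
                    epoch=db.epoch, fingerprint=db.params_fingerprint,
                    backend_tag=db.backend_tag,
                    loader=lambda i: db.chunks[i], public_keys=keys)


def load_db(store_path: str | Path, keys: KeyMaterial) -> HostedDB:
    """Load a disk store written by :func:`bedcrypt.dbstore.save_store`."""
    store_path = Path(store_path)
    meta = read_store_meta(store_path)
    params = HEParams(
        poly_degree=meta["poly_degree"],
        plain_modulus_bits=meta["plain_modulus_bits"],
        security_bits=meta["security_bits"],
        coeff_modulus_bits=tuple(meta["coeff_modulus_bits"]),
        special_count=meta["special_count"],
    )
    if params.fingerprint() != meta["fingerprint"]:
        raise StoreError("store params file is inconsistent with its fingerprint")
    if keys.params.fingerprint() != meta["fingerprint"]:
        raise StoreError("key material does not match store parameters")
    for i in range(meta["chunk_count"]):
        if not (store_path / f"chunk_{i:05d}.bin").exists():
            raise StoreError(f"missing chunk {i} of {meta['chunk_count']}")
    if keys.has_secret:
        keys = keys.public_only()

    def loader(i: int) -> CipherChunk:
        raw = (store_path / f"chunk_{i:05d}.bin").read_bytes()
        return CipherChunk.from_bytes(raw, expected_backend=meta["backend"],
                                      params=params)

    return HostedDB(chunk_count=meta["chunk_count"],
                    chunk_size=meta["chunk_size"], epoch=meta["epoch"],
                    fingerprint=meta["fingerprint"],
                    backend_tag=meta["backend"], loader=loader,
                    public_keys=keys)


def extract(handle: HostedDB, sel: Selector) -> CipherChunk:
    """The fixed kernel: one logical rotation, one plaintext mask."""
    if not 0 <= sel.physical_chunk_id < handle.chunk_count:
        raise AddressingError(f"chunk id {sel.physical_chunk_id} out of range")
    backend = get_backend(handle.backend_tag)
    chunk = handle.chunk(sel.physical_chunk_id)
    rotated = backend.bring_to_front(chunk, sel.slot_offset, handle.keys)
    return backend.mask_front(rotated, handle.keys)


def extract_batch(handle: HostedDB, req: ExtractionRequest,
                  execution_order: list[int] | None = None) -> ExtractionResponse:
    """Execute a batch; output order always equals request order.

    ``execution_order`` permutes internal processing (used to exercise the
    order-preservation contract under out-of-order completion).
    """
    if req.epoch != handle.epoch:
        raise StalePlanError(
            f"request epoch {req.epoch} != hosted epoch {handle.epoch}")
    req.validate(handle.chunk_count, handle.chunk_size)
    backend = get_backend(handle.backend_tag)
    n = len(req.selectors)
    order = execution_order if execution_order is not None else range(n)
    slots: list[CipherChunk | None] = [None] * n
    per_selector_ops = []
    t0 = time.monotonic()
    for idx in order:
        sel = req.selectors[idx]
        before = backend.counter.snapshot()
        slots[idx] = extract(handle, sel)
        after = backend.counter.snapshot()
        per_selector_ops.append({k: after[k] - before[k] for k in after})
    if any(s is None for s in slots):
        raise ProtocolError("execution order did not cover every selector")
    handle.last_batch_stats = {
        "selectors": n,
        "wall_s": time.monotonic() - t0,
        "per_selector_ops": per_selector_ops,
    }
    results = [(sel.ordinal, slots[i]) for i, sel in enumerate(req.selectors)]
    return ExtractionResponse(handle.epoch, results)


# -------------------------------------------------------------- transports

class LoopbackTransport:
    """In-process request/response (tests and library use)."""

    def __init__(self, handle: HostedDB):
        self.handle = handle

    def query(self, req: ExtractionRequest) -> ExtractionResponse:
        return extract_batch(self.handle, req)


def serialize_request(req: ExtractionRequest) -> bytes:
    head = struct.pack("<QI", req.epoch, len(req.selectors))
    body = b"".join(struct.pack("<QII", s.ordinal, s.physical_chunk_id,
                                s.slot_offset) for s in req.selectors)
    return b"BCRQ" + head + body


def deserialize_request(raw: bytes) -> ExtractionRequest:
    if raw[:4] != b"BCRQ":
        raise ProtocolError("bad request magic")
    epoch, n = struct.unpack("<QI", raw[4:16])
    sels = []
    off = 16
    for _ in range(n):
        ordinal, cid, slot = struct.unpack("<QII", raw[off:off + 16])
        sels.append(Selector(cid, slot, ordinal))
        off += 16
    return ExtractionRequest(epoch, sels)


def serialize_response(resp: ExtractionResponse) -> bytes:
    parts = [b"BCRS", struct.pack("<QI", resp.epoch, len(resp.results))]
    for ordinal, chunk in resp.results:
        blob = chunk.to_bytes()
        parts.append(struct.pack("<QI", ordinal, len(blob)))
        parts.append(blob)
    return b"".join(parts)


def deserialize_response(raw: bytes) -> ExtractionResponse:
    if raw[:4] != b"BCRS":
        raise ProtocolError("bad response magic")
    epoch, n = struct.unpack("<QI", raw[4:16])
    off = 16
    results = []
    for _ in range(n):
        ordinal, blen = struct.unpack("<QI", raw[off:off + 12])
        off += 12
        results.append((ordinal, CipherChunk.from_bytes(raw[off:off + blen])))
        off += blen
    return ExtractionResponse(epoch, results)


class DirTransport:
    """Filesystem mailbox: request.bin in, response.bin out."""

    def __init__(self, mailbox: str | Path, handle: HostedDB | None = None):
        self.mailbox = Path(mailbox)
        self.mailbox.mkdir(parents=True, exist_ok=True)
        self.handle = handle

    def query(self, req: ExtractionRequest) -> ExtractionResponse:
        (self.mailbox / "request.bin").write_bytes(serialize_request(req))
        if self.handle is not None:  # co-located server: serve immediately
            self.serve_once()
        resp_path = self.mailbox / "response.bin"
        if not resp_path.exists():
            raise ProtocolError("no response in mailbox")
        return deserialize_response(resp_path.read_bytes())

    def serve_once(self):
        if self.handle is None:
            raise ProtocolError("mailbox transport has no hosted DB")
        req = deserialize_request((self.mailbox / "request.bin").read_bytes())
        resp = extract_batch(self.handle, req)
        (self.mailbox / "response.bin").write_bytes(serialize_response(resp))


class TcpTransport:
    """Length-prefixed request/response over one TCP connection per query."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0,
                 handle: HostedDB | None = None):
        self.host = host
        self.port = port
        self.handle = handle
        self._sock: socket.socket | None = None

    def _recv_exact(self, conn, n: int) -> bytes:
        buf = b""
        while len(buf) < n:
            part = conn.recv(n - len(buf))
            if not part:
                raise ProtocolError("connection closed mid-message")
            buf += part
        return buf

    def listen(self):
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._sock.bind((self.host, self.port))
        self.port = self._sock.getsockname()[1]
        self._sock.listen(4)

    def serve_once(self):
        if self.handle is None or self._sock is None:
            raise ProtocolError("tcp transport not set up for serving")
        conn, _ = self._sock.accept()
        with conn:
            (n,) = struct.unpack("<Q", self._recv_exact(conn, 8))
            req = deserialize_request(self._recv_exact(conn, n))
            try:
                resp = extract_batch(self.handle, req)
                payload = serialize_response(resp)
            except (StalePlanError, AddressingError, ProtocolError) as exc:
                payload = b"BCER" + json.dumps(
                    {"error": type(exc).__name__, "message": str(exc)}).encode()
            conn.sendall(struct.pack("<Q", len(payload)) + payload)

    def close(self):
        if self._sock is not None:
            self._sock.close()
            self._sock = None

    def query(self, req: ExtractionRequest) -> ExtractionResponse:
        with socket.create_connection((self.host, self.port)) as conn:
            raw = serialize_request(req)
            conn.sendall(struct.pack("<Q", len(raw)) + raw)
            (n,) = struct.unpack("<Q", self._recv_exact(conn, 8))
            payload = self._recv_exact(conn, n)
        if payload[:4] == b"BCER":
            err = json.loads(payload[4:].decode())
            exc_cls = {"StalePlanError": StalePlanError,
                       "AddressingError": AddressingError}.get(
                           err["error"], ProtocolError)
            raise exc_cls(err["message"])
        return deserialize_response(payload)
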