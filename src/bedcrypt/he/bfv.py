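"""Lattice BFV backend (RNS, pure NumPy).

Implements textbook BFV over R_q = Z_q[x]/(x^N+1) with:

* SIMD batching: N slots as two rows of N/2, encoded through an NTT mod t;
* per-coefficient scaled encoding round(q*m/t) so fresh noise is independent
  of the plaintext magnitude;
* slot rotation via the Galois automorphisms x -> x^(3^k) (row rotation) and
  x -> x^(2N-1) (row swap), with hybrid key switching through special primes;
* plaintext masking as a single plaintext multiplication;
* exact invariant-noise budget measurement (requires the secret key).

Arbitrary rotations compose power-of-two steps, so only log2(N/2) + 1 Galois
keys exist.  No ciphertext-ciphertext multiplication and no relinearization
anywhere in the extraction circuit.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ..errors import CorruptionError, KeyError_, ParameterError
from .base import CipherChunk, HEBackend, KeyMaterial
from .ntt import NTT, apply_automorphism
from .params import HEParams

_SIGMA = 3.2  # error distribution width (standard HE choice)


class _Context:
    """Per-parameter precomputation: primes, NTT tables, CRT constants,
    slot-order permutation, cached mask plaintext."""

    def __init__(self, params: HEParams):
        self.params = params
        n = params.poly_degree
        self.n = n
        self.t = params.plain_modulus
        qs, ps = params.coeff_modulus()
        self.qs = qs
        self.ps = ps
        self.mods = qs + ps
        self.kq = len(qs)
        self.kp = len(ps)
        self.Q = 1
        for q in qs:
            self.Q *= q
        self.P = 1
        for p in ps:
            self.P *= p
        self.ntts = [NTT(p, n) for p in self.mods]
        self.ntt_t = NTT(self.t, n)
        self.qs_arr = np.array(qs, dtype=np.int64)[:, None]
        self.pinv_mod_q = np.array([pow(self.P, -1, q) for q in qs], dtype=np.int64)
        self.p_mod_q = np.array([self.P % q for q in qs], dtype=np.int64)
        self.crt_coef = [self.Q // q * pow(self.Q // q, -1, q) % self.Q for q in qs]
        if self.kp > 1:
            self.crt_coef_p = [self.P // p * pow(self.P // p, -1, p) % self.P
                               for p in ps]
        self._build_slot_map()
        self._mask_ntt = None  # lazy per-modulus NTT of the e0 mask plaintext

    def _build_slot_map(self):
        n, t = self.n, self.t
        mono = np.zeros(n, dtype=np.int64)
        mono[1] = 1
        pts = self.ntt_t.fwd(mono)  # value at position j = evaluation point j
        pos = {int(v): j for j, v in enumerate(pts)}
        two_n = 2 * n
        psi = self.ntt_t.psi
        order = np.empty(n, dtype=np.int64)
        g = 1
        for i in range(n // 2):
            order[i] = pos[pow(psi, g, t)]
            order[n // 2 + i] = pos[pow(psi, two_n - g, t)]
            g = g * 3 % two_n
        self.slot_to_pos = order

    def encode(self, slots: np.ndarray) -> np.ndarray:
        ntt_form = np.empty(self.n, dtype=np.int64)
        ntt_form[self.slot_to_pos] = np.asarray(slots, dtype=np.int64) % self.t
        return self.ntt_t.inv(ntt_form)

    def decode(self, poly: np.ndarray) -> np.ndarray:
        return self.ntt_t.fwd(poly % self.t)[self.slot_to_pos]

    def galois_elt(self, step: int) -> int:
        return pow(3, step, 2 * self.n)

    @property
    def row_swap_elt(self) -> int:
        return 2 * self.n - 1

    def key_elts(self) -> list[int]:
        steps = [1 << j for j in range((self.n // 2).bit_length() - 1)]
        return [self.galois_elt(s) for s in steps] + [self.row_swap_elt]

    def mask_ntt(self):
        if self._mask_ntt is None:
            e0 = np.zeros(self.n, dtype=np.int64)
            e0[0] = 1
            pt = self.encode(e0)
            pt = np.where(pt > self.t // 2, pt - self.t, pt)  # centered lift
            self._mask_ntt = np.stack(
                [self.ntts[i].fwd(pt % q) for i, q in enumerate(self.qs)])
        return self._mask_ntt


@lru_cache(maxsize=8)
def _get_context(params: HEParams) -> _Context:
    return _Context(params)


@dataclass
class _PublicKeys:
    pk0: np.ndarray                      # (kq, n) NTT domain
    pk1: np.ndarray
    galois: dict[int, tuple[np.ndarray, np.ndarray]]  # elt -> ksk (kq, kqp, n)
    rng: np.random.Generator             # encryption randomness


class BFVBackend(HEBackend):
    tag = "bfv"

    # ------------------------------------------------------------------ keys
    def keygen(self, params: HEParams, seed: int | None = None) -> KeyMaterial:
        ctx = _get_context(params)
        rng = np.random.default_rng(seed)
        s = rng.integers(-1, 2, ctx.n, dtype=np.int64)
        s_ntt = [ctx.ntts[j].fwd(s % m) for j, m in enumerate(ctx.mods)]
        a = self._uniform(rng, ctx, ctx.qs)
        e = self._gauss(rng, ctx)
        pk0 = np.stack([
            (-(ctx.ntts[i].fwd(a[i]) * s_ntt[i] % q) - ctx.ntts[i].fwd(e % q)) % q
            for i, q in enumerate(ctx.qs)])
        pk1 = np.stack([ctx.ntts[i].fwd(a[i]) for i in range(ctx.kq)])
        galois = {}
        for elt in ctx.key_elts():
            galois[elt] = self._gen_ksk(ctx, rng, s, s_ntt, elt)
        public = _PublicKeys(pk0, pk1, galois, rng)
        return KeyMaterial(params, public, s)

    def _gen_ksk(self, ctx, rng, s, s_ntt, elt):
        """Hybrid key-switching key: tau_elt(s) -> s, digits = ct primes."""
        n = ctx.n
        tau_s = self._automorph_signed(s, elt, n)
        ksk0 = np.empty((ctx.kq, ctx.kq + ctx.kp, n), dtype=np.int64)
        ksk1 = np.empty_like(ksk0)
        for i in range(ctx.kq):
            a = self._uniform(rng, ctx, ctx.mods)
            e = self._gauss(rng, ctx)
            for j, m in enumerate(ctx.mods):
                nt = ctx.ntts[j]
                a_ntt = nt.fwd(a[j])
                b = (-(a_ntt * s_ntt[j] % m) - nt.fwd(e % m)) % m
                if j == i:
                    b = (b + nt.fwd((ctx.P % m) * (tau_s % m) % m)) % m
                ksk0[i, j] = b
                ksk1[i, j] = a_ntt
        return ksk0, ksk1

    @staticmethod
    def _automorph_signed(poly, elt, n):
        idx = (np.arange(n) * elt) % (2 * n)
        sign = np.where(idx >= n, -1, 1)
        out = np.zeros(n, dtype=np.int64)
        out[idx % n] = sign * poly
        return out

    @staticmethod
    def _uniform(rng, ctx, mods):
        return np.stack([rng.integers(0, m, ctx.n, dtype=np.int64) for m in mods])

    @staticmethod
    def _gauss(rng, ctx):
        return np.rint(rng.normal(0.0, _SIGMA, ctx.n)).astype(np.int64)

    # ------------------------------------------------------------- encrypt
    def encrypt_chunk(self, values, keys: KeyMaterial) -> CipherChunk:
        ctx = _get_context(keys.params)
        values = self._check_values(values, keys.params)
        pub: _PublicKeys = keys.public_part
        m_poly = ctx.encode(values)
        # scale each coefficient as round(Q*m/t): keeps fresh noise ~t*e
        scaled = (2 * ctx.Q * m_poly.astype(object) + ctx.t) // (2 * ctx.t)
        rng = pub.rng
        u = rng.integers(-1, 2, ctx.n, dtype=np.int64)
        e0 = self._gauss(rng, ctx)
        e1 = self._gauss(rng, ctx)
        c0 = np.empty((ctx.kq, ctx.n), dtype=np.int64)
        c1 = np.empty_like(c0)
        for i, q in enumerate(ctx.qs):
            nt = ctx.ntts[i]
            u_ntt = nt.fwd(u % q)
            sm = (scaled % q).astype(np.int64)
            c0[i] = (nt.inv(pub.pk0[i] * u_ntt % q) + e0 + sm) % q
            c1[i] = (nt.inv(pub.pk1[i] * u_ntt % q) + e1) % q
        self.counter.encrypts += 1
        return CipherChunk(self.tag, keys.params.fingerprint(), (c0, c1))

    # -------------------------------------------------------------- rotate
    def bring_to_front(self, chunk: CipherChunk, offset: int,
                       keys: KeyMaterial) -> CipherChunk:
        ctx = _get_context(keys.params)
        offset = self._check_offset(offset, keys.params)
        self._check_chunk(chunk, keys.params)
        ct = chunk.payload
        half = ctx.n // 2
        self.counter.rotations += 1
        if offset >= half:
            ct = self._apply_galois(ctx, keys, ct, ctx.row_swap_elt)
            offset -= half
        j = 0
        while offset:
            if offset & 1:
                ct = self._apply_galois(ctx, keys, ct, ctx.galois_elt(1 << j))
            offset >>= 1
            j += 1
        if ct is chunk.payload:  # offset 0: identity rotation, fresh copy
            ct = (ct[0].copy(), ct[1].copy())
        return CipherChunk(self.tag, chunk.fingerprint, ct, dict(chunk.meta))

    def _apply_galois(self, ctx, keys, ct, elt):
        pub: _PublicKeys = keys.public_part
        if elt not in pub.galois:
            raise KeyError_(f"no Galois key for element {elt}")
        self.counter.galois += 1
        n = ctx.n
        c0 = np.stack([apply_automorphism(ct[0][i], elt, n, q)
                       for i, q in enumerate(ctx.qs)])
        c1 = np.stack([apply_automorphism(ct[1][i], elt, n, q)
                       for i, q in enumerate(ctx.qs)])
        ksk0, ksk1 = pub.galois[elt]
        kqp = ctx.kq + ctx.kp
        acc0 = np.empty((kqp, n), dtype=np.int64)
        acc1 = np.empty((kqp, n), dtype=np.int64)
        for j, m in enumerate(ctx.mods):
            nt = ctx.ntts[j]
            d_ntt = nt.fwd(c1 % m)  # (kq, n): digit i = c1 residue mod q_i
            a0 = np.zeros(n, dtype=np.int64)
            a1 = np.zeros(n, dtype=np.int64)
            for i in range(ctx.kq):
                # products are reduced, so the running sums stay < kq * m
                a0 += d_ntt[i] * ksk0[i, j] % m
                a1 += d_ntt[i] * ksk1[i, j] % m
            acc0[j] = nt.inv(a0 % m)
            acc1[j] = nt.inv(a1 % m)
        out0 = self._mod_down(ctx, acc0)
        out1 = self._mod_down(ctx, acc1)
        return ((c0 + out0) % ctx.qs_arr, out1)

    def _mod_down(self, ctx, acc):
        """round(acc / P) over the ciphertext primes (acc lives mod Q*P)."""
        if ctx.kp == 1:
            p = ctx.ps[0]
            xp = acc[ctx.kq].astype(object)
            xp = np.where(xp > p // 2, xp - p, xp)
        else:
            xp = np.zeros(ctx.n, dtype=object)
            for j in range(ctx.kp):
                xp += acc[ctx.kq + j].astype(object) * ctx.crt_coef_p[j]
            xp %= ctx.P
            xp = np.where(xp > ctx.P // 2, xp - ctx.P, xp)
        out = np.empty((ctx.kq, ctx.n), dtype=np.int64)
        for i, q in enumerate(ctx.qs):
            xpq = (xp % q).astype(np.int64)
            out[i] = (acc[i] - xpq) % q * ctx.pinv_mod_q[i] % q
        return out

    # ---------------------------------------------------------------- mask
    def mask_front(self, chunk: CipherChunk, keys: KeyMaterial) -> CipherChunk:
        ctx = _get_context(keys.params)
        self._check_chunk(chunk, keys.params)
        mask = ctx.mask_ntt()
        out = []
        for comp in chunk.payload:
            r = np.empty_like(comp)
            for i, q in enumerate(ctx.qs):
                nt = ctx.ntts[i]
                r[i] = nt.inv(nt.fwd(comp[i]) * mask[i] % q)
            out.append(r)
        self.counter.masks += 1
        return CipherChunk(self.tag, chunk.fingerprint, tuple(out), dict(chunk.meta))

    # ------------------------------------------------------------- decrypt
    def decrypt_chunk(self, chunk: CipherChunk, keys: KeyMaterial) -> np.ndarray:
        if not keys.has_secret:
            raise KeyError_("decryption requires the secret key")
        if self.noise_budget(chunk, keys) <= 0:
            raise CorruptionError("noise budget exhausted; decryption unreliable")
        ctx = _get_context(keys.params)
        w = self._crt_q(ctx, self._dot_secret(ctx, chunk.payload, keys.secret_part))
        m = (2 * ctx.t * w + ctx.Q) // (2 * ctx.Q) % ctx.t
        self.counter.decrypts += 1
        return ctx.decode(m.astype(np.int64))

    def noise_budget(self, chunk: CipherChunk, keys: KeyMaterial) -> int:
        if not keys.has_secret:
            raise KeyError_("noise budget measurement requires the secret key")
        ctx = _get_context(keys.params)
        self._check_chunk(chunk, keys.params)
        w = self._crt_q(ctx, self._dot_secret(ctx, chunk.payload, keys.secret_part))
        v = (ctx.t * w) % ctx.Q
        v = np.where(v > ctx.Q // 2, v - ctx.Q, v)
        mx = int(np.max(np.abs(v)))
        if mx == 0:
            return ctx.Q.bit_length() - 1
        return max(0, (ctx.Q // (2 * mx)).bit_length() - 1)

    def _dot_secret(self, ctx, ct, s):
        out = np.empty((ctx.kq, ctx.n), dtype=np.int64)
        for i, q in enumerate(ctx.qs):
            nt = ctx.ntts[i]
            s_ntt = nt.fwd(s % q)
            out[i] = (ct[0][i] + nt.inv(nt.fwd(ct[1][i]) * s_ntt % q)) % q
        return out

    @staticmethod
    def _crt_q(ctx, arr):
        acc = np.zeros(ctx.n, dtype=object)
        for i in range(ctx.kq):
            acc += arr[i].astype(object) * ctx.crt_coef[i]
        acc %= ctx.Q
        return np.where(acc > ctx.Q // 2, acc - ctx.Q, acc)

    # ------------------------------------------------------- serialization
    def _serialize_payload(self, payload) -> bytes:
        c0, c1 = payload
        k, n = c0.shape
        return struct.pack("<II", k, n) + c0.tobytes() + c1.tobytes()

    def _deserialize_payload(self, blob: bytes, params: HEParams | None):
        k, n = struct.unpack("<II", blob[:8])
        body = np.frombuffer(blob[8:], dtype=np.int64)
        if body.size != 2 * k * n:
            raise ParameterError("truncated ciphertext payload")
        c0 = body[:k * n].reshape(k, n).copy()
        c1 = body[k * n:].reshape(k, n).copy()
        return (c0, c1)

    def _check_chunk(self, chunk: CipherChunk, params: HEParams):
        if chunk.backend != self.tag:
            raise ParameterError(
                f"chunk belongs to backend '{chunk.backend}', not '{self.tag}'")
        if chunk.fingerprint != params.fingerprint():
            raise ParameterError("chunk/params fingerprint mismatch")
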