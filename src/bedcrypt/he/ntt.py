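"""Negacyclic number-theoretic transform modulo word-sized primes.

Works on int64 arrays of shape (..., n) with all values in [0, p).  Primes
are restricted to 31 bits so every butterfly product fits in a signed 64-bit
integer without Barrett/Montgomery machinery.
"""

from __future__ import annotations

import numpy as np


def _primitive_2n_root(p: int, two_n: int) -> int:
    for g in range(2, 10000):
        r = pow(g, (p - 1) // two_n, p)
        if pow(r, two_n // 2, p) != 1:
            return r
    raise ValueError(f"no primitive {two_n}-th root mod {p}")


def _bitrev(x: int, bits: int) -> int:
    r = 0
    for _ in range(bits):
        r = (r << 1) | (x & 1)
        x >>= 1
    return r


class NTT:
    """Forward/inverse negacyclic NTT for Z_p[x]/(x^n + 1)."""

    def __init__(self, p: int, n: int):
        if p.bit_length() > 31:
            raise ValueError("prime too large for int64 butterflies")
        self.p = p
        self.n = n
        logn = n.bit_length() - 1
        psi = _primitive_2n_root(p, 2 * n)
        self.psi = psi
        ipsi = pow(psi, p - 2, p)
        self.psi_rev = np.array(
            [pow(psi, _bitrev(i, logn), p) for i in range(n)], dtype=np.int64)
        self.ipsi_rev = np.array(
            [pow(ipsi, _bitrev(i, logn), p) for i in range(n)], dtype=np.int64)
        self.n_inv = pow(n, p - 2, p)

    def fwd(self, a: np.ndarray) -> np.ndarray:
        """Cooley–Tukey decimation-in-time; output in bit-reversed order."""
        p, n = self.p, self.n
        a = np.ascontiguousarray(a, dtype=np.int64).copy()
        shp = a.shape
        t, m = n, 1
        while m < n:
            t //= 2
            v = a.reshape(shp[:-1] + (m, 2, t))
            s = self.psi_rev[m:2 * m, None]
            u = v[..., 0, :].copy()
            w = v[..., 1, :] * s % p
            v[..., 0, :] = (u + w) % p
            v[..., 1, :] = (u - w) % p
            m *= 2
        return a

    def inv(self, a: np.ndarray) -> np.ndarray:
        """Gentleman–Sande inverse; consumes bit-reversed order."""
        p, n = self.p, self.n
        a = np.ascontiguousarray(a, dtype=np.int64).copy()
        shp = a.shape
        t, m = 1, n
        while m > 1:
            h = m // 2
            v = a.reshape(shp[:-1] + (h, 2, t))
            s = self.ipsi_rev[h:2 * h, None]
            u = v[..., 0, :].copy()
            w = v[..., 1, :].copy()
            v[..., 0, :] = (u + w) % p
            v[..., 1, :] = (u - w) % p * s % p
            t *= 2
            m = h
        return a * self.n_inv % p


def apply_automorphism(res: np.ndarray, elt: int, n: int, p: int) -> np.ndarray:
    """x -> x^elt on a coefficient-domain residue polynomial mod p."""
    idx = (np.arange(n) * elt) % (2 * n)
    neg = idx >= n
    idx = idx % n
    out = np.zeros(n, dtype=np.int64)
    out[idx] = np.where(neg, (p - res) % p, res)
    return out
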