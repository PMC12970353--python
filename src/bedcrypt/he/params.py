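"""BFV parameter sets.

The scheme operates on the ring R_q = Z_q[x]/(x^N + 1) with a prime plaintext
modulus t = 1 (mod 2N) so the N slots batch.  The coefficient modulus q is a
chain of NTT-friendly word-sized primes; the trailing primes of the chain are
*special* primes used only inside hybrid key switching (ciphertexts live
modulo the product of the leading primes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache

from ..errors import ParameterError

#: Default coefficient-modulus bit chains per (poly_degree, security_bits).
#: Format: (ciphertext prime bits, special prime bits).  Totals follow the
#: homomorphic-encryption standard's maximum modulus sizes for 128-bit
#: security (109 bits at N=4096, 218 bits at N=8192, 438 at N=16384).
DEFAULT_CHAINS: dict[tuple[int, int], tuple[tuple[int, ...], tuple[int, ...]]] = {
    (4096, 128): ((29, 29, 29), (22,)),
    (8192, 128): ((30, 29, 29, 29, 29, 29), (22, 21)),
    (16384, 128): ((30,) * 13, (24, 24)),
}

_MR_BASES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)


def is_prime(n: int) -> bool:
    """Deterministic Miller–Rabin for n < 3.3e24."""
    if n < 2:
        return False
    for p in _MR_BASES:
        if n % p == 0:
            return n == p
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    for a in _MR_BASES:
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


def batching_prime(bits: int, two_n: int, ascending: bool = True,
                   exclude: frozenset[int] = frozenset()) -> int:
    """Smallest (or largest) prime with the given bit length and p = 1 (mod 2N)."""
    if ascending:
        p = ((1 << (bits - 1)) // two_n + 1) * two_n + 1
        step = two_n
    else:
        p = ((1 << bits) - 1) // two_n * two_n + 1
        step = -two_n
    while (1 << (bits - 1)) <= p < (1 << bits):
        if is_prime(p) and p not in exclude:
            return p
        p += step
    raise ParameterError(
        f"no {bits}-bit prime congruent to 1 mod {two_n}; "
        f"plaintext/coefficient modulus incompatible with N={two_n // 2}")


@dataclass(frozen=True)
class HEParams:
    """Ring dimension, plaintext modulus size, and coefficient modulus chain.

    ``coeff_modulus_bits`` empty means: use the backend default chain for
    (poly_degree, security_bits).  When given explicitly, the final
    ``special_count`` entries are treated as key-switching special primes.
    """

    poly_degree: int = 8192
    plain_modulus_bits: int = 30
    security_bits: int = 128
    coeff_modulus_bits: tuple[int, ...] = ()
    special_count: int = 1

    def __post_init__(self):
        n = self.poly_degree
        if n < 4096 or n & (n - 1) != 0:
            raise ParameterError(
                f"poly_degree must be a power of two >= 4096, got {n}")
        if not 2 <= self.plain_modulus_bits <= 60:
            raise ParameterError(
                f"plain_modulus_bits out of range: {self.plain_modulus_bits}")
        if not self.coeff_modulus_bits:
            key = (n, self.security_bits)
            if key not in DEFAULT_CHAINS:
                raise ParameterError(
                    f"no default coefficient modulus for N={n} at "
                    f"{self.security_bits}-bit security")
        elif not 1 <= self.special_count < len(self.coeff_modulus_bits):
            raise ParameterError("special_count must leave >= 1 ciphertext prime")

    @property
    def slot_count(self) -> int:
        return self.poly_degree

    def chain_bits(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """(ciphertext prime bits, special prime bits)."""
        if self.coeff_modulus_bits:
            k = len(self.coeff_modulus_bits) - self.special_count
            return tuple(self.coeff_modulus_bits[:k]), tuple(self.coeff_modulus_bits[k:])
        return DEFAULT_CHAINS[(self.poly_degree, self.security_bits)]

    @property
    def plain_modulus(self) -> int:
        return _plain_modulus(self.poly_degree, self.plain_modulus_bits)

    def coeff_modulus(self) -> tuple[list[int], list[int]]:
        """Realized (ciphertext primes, special primes)."""
        return _coeff_modulus(self.poly_degree, self.plain_modulus_bits,
                              self.chain_bits())

    def total_coeff_modulus_bits(self) -> int:
        """Sum of the bit lengths of all primes in the chain."""
        qs, ps = self.coeff_modulus()
        return sum(p.bit_length() for p in qs + ps)

    def fingerprint(self) -> str:
        return _fingerprint(self)


@lru_cache(maxsize=None)
def _fingerprint(params: "HEParams") -> str:
    qs, ps = params.coeff_modulus()
    blob = json.dumps({
        "n": params.poly_degree, "t": params.plain_modulus,
        "qs": qs, "ps": ps,
    }, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@lru_cache(maxsize=None)
def _plain_modulus(n: int, bits: int) -> int:
    return batching_prime(bits, 2 * n, ascending=True)


@lru_cache(maxsize=None)
def _coeff_modulus(n, t_bits, chain):
    ct_bits, sp_bits = chain
    t = _plain_modulus(n, t_bits)
    used = {t}
    qs, ps = [], []
    for bits, out in ((ct_bits, qs), (sp_bits, ps)):
        for b in bits:
            p = batching_prime(b, 2 * n, ascending=False, exclude=frozenset(used))
            if p.bit_length() > 31:
                raise ParameterError(
                    f"coefficient primes are limited to 31 bits (got {b})")
            out.append(p)
            used.add(p)
    return qs, ps
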