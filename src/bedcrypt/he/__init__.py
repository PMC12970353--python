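"""Homomorphic-encryption backends: a real lattice BFV implementation and a
plaintext mock with a calibrated noise ledger, behind one interface."""

from __future__ import annotations

import os

import numpy as np

from .base import CipherChunk, HEBackend, KeyMaterial, OpCounter, rotate_slots_reference
from .params import DEFAULT_CHAINS, HEParams

_backends: dict[str, HEBackend] = {}


def get_backend(tag: str) -> HEBackend:
    """Return the (process-wide) backend instance for ``tag``."""
    if tag not in _backends:
        if tag == "bfv":
            from .bfv import BFVBackend
            _backends[tag] = BFVBackend()
        elif tag == "mock":
            from .mock import MockBackend
            _backends[tag] = MockBackend()
        else:
            raise ValueError(f"unknown HE backend '{tag}'")
    return _backends[tag]


def save_keys(keys: KeyMaterial, public_path: str, secret_path: str | None = None):
    """Persist key material: public bundle and secret key as separate files.

    The secret key never goes into the public bundle.  Only the lattice
    backend has nontrivial key material; mock keys are a stub id.
    """
    params_d = {
        "poly_degree": keys.params.poly_degree,
        "plain_modulus_bits": keys.params.plain_modulus_bits,
        "security_bits": keys.params.security_bits,
        "coeff_modulus_bits": np.array(keys.params.coeff_modulus_bits, dtype=np.int64),
        "special_count": keys.params.special_count,
    }
    pub = keys.public_part
    if isinstance(pub, dict):  # mock
        np.savez(public_path, backend="mock", key_id=pub["key_id"], **params_d)
        if secret_path is not None and keys.secret_part is not None:
            np.savez(secret_path, backend="mock", key_id=keys.secret_part["key_id"])
        return
    arrays = {"backend": "bfv", "pk0": pub.pk0, "pk1": pub.pk1,
              "galois_elts": np.array(sorted(pub.galois), dtype=np.int64),
              "enc_seed": np.int64(_rng_seed())}
    for elt, (k0, k1) in pub.galois.items():
        arrays[f"gk0_{elt}"] = k0
        arrays[f"gk1_{elt}"] = k1
    np.savez(public_path, **params_d, **arrays)
    if secret_path is not None and keys.secret_part is not None:
        np.savez(secret_path, backend="bfv", s=keys.secret_part)


def load_keys(public_path: str, secret_path: str | None = None) -> KeyMaterial:
    with np.load(public_path) as z:
        params = HEParams(
            poly_degree=int(z["poly_degree"]),
            plain_modulus_bits=int(z["plain_modulus_bits"]),
            security_bits=int(z["security_bits"]),
            coeff_modulus_bits=tuple(int(b) for b in z["coeff_modulus_bits"]),
            special_count=int(z["special_count"]),
        )
        if str(z["backend"]) == "mock":
            key_id = int(z["key_id"])
            secret = None
            if secret_path is not None and os.path.exists(secret_path):
                with np.load(secret_path) as zs:
                    secret = {"key_id": int(zs["key_id"])}
            return KeyMaterial(params, {"key_id": key_id}, secret)
        from .bfv import _PublicKeys
        galois = {int(e): (z[f"gk0_{int(e)}"], z[f"gk1_{int(e)}"])
                  for e in z["galois_elts"]}
        pub = _PublicKeys(z["pk0"].copy(), z["pk1"].copy(), galois,
                          np.random.default_rng(int(z["enc_seed"])))
    secret = None
    if secret_path is not None and os.path.exists(secret_path):
        with np.load(secret_path) as zs:
            secret = zs["s"].copy()
    return KeyMaterial(params, pub, secret)


def _rng_seed() -> int:
    return int.from_bytes(os.urandom(8), "little") >> 1


__all__ = [
    "CipherChunk", "HEBackend", "HEParams", "KeyMaterial", "OpCounter",
    "DEFAULT_CHAINS", "get_backend", "save_keys", "load_keys",
    "rotate_slots_reference",
]
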