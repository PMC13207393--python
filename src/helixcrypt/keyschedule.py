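"""Key derivation and all key-dependent material.

A user passphrase is stretched with PBKDF2-HMAC-SHA256 into a 512-bit master
key. Everything else the cipher needs is derived deterministically from that
master key with domain-separated hashes:

* the encoding-table index (SHA-256 of the master key, mod 24),
* the one-time-pad keystream (HMAC-SHA256 in counter mode),
* the chaotic permutation (logistic map x_{n+1} = r x_n (1-x_n) seeded from
  the master key; the ranking of the iterates is the shuffle).

Every function here is a pure function of its arguments, so encryption and
decryption regenerate identical material from the same passphrase and salt.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

MASTER_KEY_BYTES = 64  # 512 bits
SALT_BYTES = 16
DEFAULT_KDF_ITERATIONS = 600_000
N_TABLES = 24

# domain-separation labels (ours; the underlying scheme does not fix them)
_LABEL_PERM = b"helixcrypt/perm"
_LABEL_STREAM = b"helixcrypt/stream"


def _table_index(master_key: bytes) -> int:
    digest = hashlib.sha256(master_key).digest()
    return int.from_bytes(digest, "big") % N_TABLES


@dataclass(frozen=True)
class KeyMaterial:
    """Master key plus the material derived from it."""

    master_key: bytes
    salt: bytes
    kdf_iterations: int
    stream_nonce: int = 0
    table_index: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.master_key) != MASTER_KEY_BYTES:
            raise InvalidInputError(
                f"master key must be {MASTER_KEY_BYTES} bytes, "
                f"got {len(self.master_key)}"
            )
        if len(self.salt) != SALT_BYTES:
            raise InvalidInputError(f"salt must be {SALT_BYTES} bytes")
        if self.kdf_iterations < 1:
            raise InvalidInputError("kdf_iterations must be >= 1")
        object.__setattr__(self, "table_index", _table_index(self.master_key))


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic map used for the chaotic permutation.

    ``r`` must lie in the chaotic band (3.57, 4.0]; the default 3.99 keeps the
    iterates dense in (0, 1). ``burn_in`` iterations are discarded so the
    ranking does not see the transient approach to the attractor.
    """

    r: float = 3.99
    x0: float = 0.5
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if not 3.57 < self.r <= 4.0:
            raise InvalidInputError("r must lie in (3.57, 4.0]")
        if not 0.0 < self.x0 < 1.0:
            raise InvalidInputError("x0 must lie strictly inside (0, 1)")
        if self.x0 == 1.0 - 1.0 / self.r:
            raise InvalidInputError("x0 must not be the map's fixed point")
        if self.burn_in < 0:
            raise InvalidInputError("burn_in must be non-negative")


def derive_master_key(passphrase: str, salt: bytes,
                      iterations: int = DEFAULT_KDF_ITERATIONS) -> KeyMaterial:
    """Stretch a passphrase into a 512-bit master key.

    PBKDF2-HMAC-SHA256 with a 16-byte salt; identical inputs always yield
    identical key material.
    """
    if not passphrase:
        raise InvalidInputError("passphrase must be non-empty")
    if iterations < 1:
        raise InvalidInputError("iterations must be >= 1")
    if len(salt) != SALT_BYTES:
        raise InvalidInputError(f"salt must be {SALT_BYTES} bytes")
    mk = hashlib.pbkdf2_hmac("sha256", passphrase.encode("utf-8"), salt,
                             iterations, dklen=MASTER_KEY_BYTES)
    return KeyMaterial(master_key=mk, salt=salt, kdf_iterations=iterations)


def keystream(key: KeyMaterial, nonce: int, n_symbols: int) -> np.ndarray:
    """First ``n_symbols`` 2-bit symbols of the HMAC-SHA256 counter stream.

    Block i of the stream is HMAC-SHA256(master_key, label || nonce || i);
    blocks are concatenated and chopped into 2-bit symbols, so the stream has
    the prefix property: requesting more symbols extends, never changes, a
    shorter request.
    """
    if n_symbols < 1:
        raise InvalidInputError("n_symbols must be >= 1")
    if nonce < 0:
        raise InvalidInputError("nonce must be non-negative")
    n_bytes = (n_symbols + 3) // 4
    blocks = []
    prefix = _LABEL_STREAM + nonce.to_bytes(8, "big")
    for i in range((n_bytes + 31) // 32):
        blocks.append(hmac.new(key.master_key, prefix + i.to_bytes(8, "big"),
                               hashlib.sha256).digest())
    raw = np.frombuffer(b"".join(blocks)[:n_bytes], dtype=np.uint8)
    bits = np.unpackbits(raw)
    symbols = bits[0::2] * 2 + bits[1::2]
    return symbols[:n_symbols].astype(np.uint8)


def logistic_sequence(params: LogisticParams, n: int) -> np.ndarray:
    """Iterate the logistic map and return ``n`` post-burn-in values.

    Plain binary64 iteration with round-to-nearest; all values stay strictly
    inside (0, 1) for r <= 4.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    r, x = params.r, params.x0
    for _ in range(params.burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    return out


def chaotic_seed(key: KeyMaterial) -> float:
    """Key-derived x0 for the logistic map.

    First 8 bytes of SHA-256(master_key || label) as an unsigned integer,
    scaled to [0, 1) and clamped away from the endpoints so the map never
    degenerates.
    """
    digest = hashlib.sha256(key.master_key + _LABEL_PERM).digest()
    x0 = int.from_bytes(digest[:8], "big") / 2.0**64
    eps = 2.0**-20
    return min(max(x0, eps), 1.0 - eps)


def permutation_from_chaos(key: KeyMaterial,
                           params: LogisticParams | None = None,
                           n: int = 1) -> np.ndarray:
    """Key-dependent permutation of {0..n-1} from logistic-map rankings.

    Output position i holds the index of the i-th smallest chaotic value
    (gather form); ties, measure-zero in practice, break stably by original
    index. ``params.x0`` is replaced by the key-derived seed.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    base = params or LogisticParams()
    params = LogisticParams(r=base.r, x0=chaotic_seed(key),
                            burn_in=base.burn_in)
    values = logistic_sequence(params, n)
    return np.argsort(values, kind="stable")
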