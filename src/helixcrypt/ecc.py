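"""Systematic Reed-Solomon outer code over GF(2^8) with block interleaving.

The code protects the nucleotide stream against synthesis/sequencing noise:
each block of k data bytes gains n-k parity bytes and the decoder corrects up
to t = (n-k)//2 byte errors per codeword (Berlekamp-Massey, Chien search,
Forney). Codewords are round-robin interleaved in groups of
``interleave_depth`` so channel bursts spread across codewords.

Field: GF(2^8) with primitive polynomial x^8+x^4+x^3+x^2+1 (0x11d),
generator element alpha = 2, first consecutive root alpha^0. The final block
is shortened in the standard way (implicit leading zeros).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ConfigError, ECCDecodeError, FormatError

# ---------------------------------------------------------------- GF(2^8)

_PRIM = 0x11D

_EXP = np.zeros(512, dtype=np.uint8)
_LOG = np.zeros(256, dtype=np.int32)
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
_EXP[255:510] = _EXP[:255]  # wraparound so exp lookups skip the mod


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_EXP[_LOG[a] + _LOG[b]])


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(2^8)")
    if a == 0:
        return 0
    return int(_EXP[(_LOG[a] - _LOG[b]) % 255])


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0
    return int(_EXP[(_LOG[a] * n) % 255])


def _gf_mul_vec(vec: np.ndarray, scalar: int) -> np.ndarray:
    """Multiply a uint8 vector by a scalar in GF(2^8)."""
    if scalar == 0:
        return np.zeros_like(vec)
    out = np.zeros_like(vec)
    nz = vec != 0
    out[nz] = _EXP[_LOG[vec[nz]] + _LOG[scalar]]
    return out


def _gf_poly_eval_many(poly: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Evaluate poly (highest-degree coefficient first) at many points."""
    acc = np.zeros(points.size, dtype=np.uint8)
    for coef in poly:
        nz = acc != 0
        acc[nz] = _EXP[_LOG[acc[nz]] + _LOG[points[nz]]]
        acc ^= coef
    return acc


# ---------------------------------------------------------------- config

@dataclass(frozen=True)
class CodeConfig:
    """Reed-Solomon code parameters.

    The default heavy-parity profile (255, 51) corrects t = 102 byte errors
    per codeword, enough that an 8% per-base substitution channel (~28.4%
    per byte) is corrected with overwhelming probability; the lighter
    (255, 223) profile suits clean archival channels.
    """

    n: int = 255
    k: int = 51
    interleave_depth: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.k < self.n <= 255:
            raise ConfigError("require 1 <= k < n <= 255")
        if (self.n - self.k) // 2 < 1:
            raise ConfigError("correction capacity t must be >= 1")
        if self.interleave_depth < 1:
            raise ConfigError("interleave_depth must be >= 1")

    @property
    def t(self) -> int:
        """Correctable byte errors per codeword."""
        return (self.n - self.k) // 2

    @property
    def nsym(self) -> int:
        return self.n - self.k


@lru_cache(maxsize=8)
def _generator_poly(nsym: int) -> tuple[int, ...]:
    """g(x) = prod_{i=0}^{nsym-1} (x - alpha^i), highest degree first."""
    g = [1]
    for i in range(nsym):
        root = gf_pow(2, i)
        new = [0] * (len(g) + 1)
        for j, c in enumerate(g):
            new[j] ^= c
            new[j + 1] ^= gf_mul(c, root)
        g = new
    return tuple(g)


# ---------------------------------------------------------------- framing

def _block_lengths(data_len: int, cfg: CodeConfig) -> list[int]:
    """Data bytes per codeword; the last block is shortened, never empty."""
    if data_len == 0:
        return []
    full, rem = divmod(data_len, cfg.k)
    lengths = [cfg.k] * full
    if rem:
        lengths.append(rem)
    return lengths


def _interleave_order(lengths: list[int], depth: int) -> np.ndarray:
    """Transmission order of codeword bytes, round-robin in groups.

    Codewords are grouped ``depth`` at a time; within a group bytes are sent
    column-first (byte 0 of every codeword, then byte 1, ...), so a channel
    burst of length B costs each codeword at most ceil(B / group size)
    errors. Returns indices into the plain concatenation of codewords.
    """
    order: list[int] = []
    offsets = np.cumsum([0] + lengths)
    for g in range(0, len(lengths), depth):
        group = list(range(g, min(g + depth, len(lengths))))
        longest = max(lengths[i] for i in group)
        for col in range(longest):
            for cw in group:
                if col < lengths[cw]:
                    order.append(offsets[cw] + col)
    return np.asarray(order, dtype=np.int64)


# ---------------------------------------------------------------- encode

def _encode_block(msg: np.ndarray, nsym: int) -> np.ndarray:
    """Systematic codeword: message followed by parity."""
    gen = np.asarray(_generator_poly(nsym)[1:], dtype=np.uint8)
    work = np.zeros(msg.size + nsym, dtype=np.uint8)
    work[:msg.size] = msg
    for i in range(msg.size):
        coef = work[i]
        if coef:
            work[i + 1:i + 1 + nsym] ^= _gf_mul_vec(gen, int(coef))
    out = np.empty(msg.size + nsym, dtype=np.uint8)
    out[:msg.size] = msg
    out[msg.size:] = work[msg.size:]
    return out


def rs_encode(data: bytes, cfg: CodeConfig) -> bytes:
    """Encode ``data`` into interleaved systematic RS codewords."""
    arr = np.frombuffer(bytes(data), dtype=np.uint8)
    lengths = _block_lengths(arr.size, cfg)
    if not lengths:
        return b""
    codewords = []
    pos = 0
    for L in lengths:
        codewords.append(_encode_block(arr[pos:pos + L], cfg.nsym))
        pos += L
    stream = np.concatenate(codewords)
    order = _interleave_order([cw.size for cw in codewords],
                              cfg.interleave_depth)
    return stream[order].tobytes()


# ---------------------------------------------------------------- decode

def _syndromes(cw: np.ndarray, nsym: int) -> np.ndarray:
    points = _EXP[np.arange(nsym) % 255].astype(np.uint8)  # alpha^0..alpha^{nsym-1}
    return _gf_poly_eval_many(cw, points)


def _gf_dot(a: np.ndarray, b: np.ndarray) -> int:
    """XOR-accumulated GF(2^8) inner product."""
    nz = (a != 0) & (b != 0)
    if not nz.any():
        return 0
    prods = _EXP[_LOG[a[nz]] + _LOG[b[nz]]]
    return int(np.bitwise_xor.reduce(prods))


def _berlekamp_massey(synd: np.ndarray, nsym: int) -> np.ndarray:
    """Error-locator polynomial (lowest-degree-first coefficients)."""
    C = np.zeros(nsym + 1, dtype=np.uint8)
    B = np.zeros(nsym + 1, dtype=np.uint8)
    C[0] = B[0] = 1
    L, m, b = 0, 1, 1
    for i in range(nsym):
        d = int(synd[i])
        if L:
            d ^= _gf_dot(C[1:L + 1], synd[i - L:i][::-1])
        if d == 0:
            m += 1
            continue
        coef = gf_div(d, b)
        if 2 * L <= i:
            T = C.copy()
            C[m:] ^= _gf_mul_vec(B[:C.size - m], coef)
            L, B, b, m = i + 1 - L, T, d, 1
        else:
            C[m:] ^= _gf_mul_vec(B[:C.size - m], coef)
            m += 1
    return C[:L + 1].copy()


def _decode_block(cw: np.ndarray, nsym: int) -> np.ndarray:
    """Correct up to t errors in one codeword; raise ECCDecodeError if not."""
    synd = _syndromes(cw, nsym)
    if not synd.any():
        return cw[:cw.size - nsym]
    locator = _berlekamp_massey(synd, nsym)
    nerr = locator.size - 1
    if nerr > nsym // 2:
        raise ECCDecodeError(f"locator degree {nerr} exceeds capacity")
    # Chien search over valid positions (shortened codeword: highest-degree
    # coefficient of the received polynomial is position 0).
    n = cw.size
    # position j (0-based from the left) corresponds to X = alpha^{n-1-j}
    exps = (n - 1 - np.arange(n)) % 255
    xs = _EXP[exps].astype(np.uint8)
    inv_xs = _EXP[(255 - exps) % 255].astype(np.uint8)
    vals = _gf_poly_eval_many(locator[::-1], inv_xs)
    err_pos = np.flatnonzero(vals == 0)
    if err_pos.size != nerr:
        raise ECCDecodeError(
            f"locator roots ({err_pos.size}) != degree ({nerr})")
    # Forney: omega(x) = [s(x) * lambda(x)] mod x^nsym, magnitudes
    # e_j = X_j * omega(X_j^-1) / lambda'(X_j^-1)   (fcr = 0)
    omega = np.zeros(nsym, dtype=np.uint8)
    for j in range(min(locator.size, nsym)):
        lj = int(locator[j])
        if lj:
            omega[j:] ^= _gf_mul_vec(synd[:nsym - j], lj)
    pts = inv_xs[err_pos]
    om_vals = _gf_poly_eval_many(omega[::-1], pts)
    # formal derivative of locator: in GF(2) only odd-power terms survive;
    # lambda'(x) = sum_i locator[2i+1] x^{2i}, i.e. a polynomial in x^2
    deriv_coeffs = locator[1::2]
    pts_sq = _EXP[(2 * _LOG[pts]) % 255].astype(np.uint8)
    pts_sq[pts == 0] = 0
    dp_vals = _gf_poly_eval_many(deriv_coeffs[::-1], pts_sq)
    if (dp_vals == 0).any():
        raise ECCDecodeError("zero derivative in Forney algorithm")
    mags = _EXP[(_LOG[om_vals] - _LOG[dp_vals]) % 255].astype(np.uint8)
    mags[om_vals == 0] = 0
    errs = _EXP[_LOG[xs[err_pos]] + _LOG[np.maximum(mags, 1)]].astype(np.uint8)
    errs[mags == 0] = 0
    corrected = cw.copy()
    corrected[err_pos] ^= errs
    if _syndromes(corrected, nsym).any():
        raise ECCDecodeError("residual syndromes after correction")
    return corrected[:corrected.size - nsym]


def rs_decode(coded: bytes, cfg: CodeConfig) -> bytes:
    """De-interleave and decode; returns data or raises :class:`ECCDecodeError`.

    The block structure is inferred from the coded length (full codewords of
    n bytes plus one optional shortened final codeword); a length that fits
    no valid framing raises :class:`FormatError`.
    """
    arr = np.frombuffer(bytes(coded), dtype=np.uint8)
    if arr.size == 0:
        return b""
    nsym = cfg.nsym
    full, rem = divmod(arr.size, cfg.n)
    lengths = [cfg.n] * full
    if rem:
        if rem <= nsym:
            raise FormatError(
                f"coded length {arr.size} inconsistent with RS({cfg.n},{cfg.k})")
        lengths.append(rem)
    order = _interleave_order(lengths, cfg.interleave_depth)
    stream = np.empty(arr.size, dtype=np.uint8)
    stream[order] = arr
    out = []
    pos = 0
    failures = []
    for bi, L in enumerate(lengths):
        try:
            out.append(_decode_block(stream[pos:pos + L], nsym))
        except ECCDecodeError as exc:
            failures.append((bi, str(exc)))
        pos += L
    if failures:
        raise ECCDecodeError(
            f"uncorrectable codewords: {[(b, m) for b, m in failures]}")
    return np.concatenate(out).tobytes()
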