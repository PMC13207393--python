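"""The multi-layer encryption pipeline and its exact inverse.

Encryption chain (all layers individually invertible):

1. plaintext bytes -> bits -> DNA under the key-selected encoding table
2. Watson-Crick complement (A<->T, C<->G)
3. DNA-XOR: 2-bit one-time-pad with the HMAC-counter keystream
4. chaotic permutation: whole-message shuffle ranked from the logistic map
5. transcription: T -> U, then a forward context-chained substitution
6. a reverse-direction context-chained substitution, so a single-symbol
   change diffuses through the entire payload in both directions

Steps 5-6 use keyed S-boxes over {A, C, G, U} indexed by the neighbouring
nucleotide *and* a 64-bit rolling context accumulated over the symbols
already processed. The accumulator is what makes diffusion complete: once
two messages differ in one symbol, their contexts never re-merge, and each
subsequent output symbol is re-randomized independently — changing with
probability 3/4 (1/2 at bit level), the ideal for a 4-letter alphabet.

An optional Reed-Solomon outer code and the biochemical constraint layer
wrap the ciphertext afterwards (see :mod:`helixcrypt.ecc` and
:mod:`helixcrypt.constraints`); both are positionwise, so channel errors
stay local and correctable.
"""

from __future__ import annotations

import hashlib
import hmac
import itertools
import secrets
from dataclasses import dataclass

import numpy as np

from . import constraints as _constraints
from .codec import (EncodingTable, bits_to_bytes, bits_to_dna, dna_to_bits,
                    enumerate_tables, text_to_bits)
from .config import EncryptionConfig
from .ecc import CodeConfig, rs_decode, rs_encode
from .errors import FormatError, InvalidInputError
from .keyschedule import (KeyMaterial, derive_master_key, keystream,
                          permutation_from_chaos)
from .nucseq import Alphabet, NucSeq, as_nucseq

FORMAT_VERSION = "helixcrypt-1"

_MASK64 = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15

#: the 24 permutations of the 2-bit values, lexicographic; shared by the
#: S-box layer (selection index -> bijection over {A,C,G,U})
_VALUE_PERMS = tuple(itertools.permutations(range(4)))
_VALUE_PERMS_INV = tuple(
    tuple(p.index(v) for v in range(4)) for p in _VALUE_PERMS
)

_CONTEXT_LABELS = (b"^", b"A", b"C", b"G", b"U")  # index 4 = start sentinel


# ------------------------------------------------------------- permutation

@dataclass(frozen=True)
class Permutation:
    """Gather-form permutation: output position i takes input position
    ``mapping[i]`` (0-based internally)."""

    mapping: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mapping, dtype=np.int64)
        object.__setattr__(self, "mapping", m)
        if m.size and (np.sort(m) != np.arange(m.size)).any():
            raise InvalidInputError("mapping must be a bijection on 0..n-1")

    def __len__(self) -> int:
        return self.mapping.size

    @classmethod
    def from_one_based(cls, key) -> "Permutation":
        return cls(np.asarray(key, dtype=np.int64) - 1)

    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(np.arange(n, dtype=np.int64))

    def inverse(self) -> "Permutation":
        inv = np.empty_like(self.mapping)
        inv[self.mapping] = np.arange(self.mapping.size)
        return Permutation(inv)


def apply_permutation(seq: NucSeq, p: Permutation) -> NucSeq:
    """output[i] = input[p[i]] (gather semantics)."""
    if len(seq) != len(p):
        raise InvalidInputError(
            f"sequence length {len(seq)} != permutation size {len(p)}")
    return NucSeq.from_values(seq.values()[p.mapping], seq.alphabet)


def invert_permutation(seq: NucSeq, p: Permutation) -> NucSeq:
    """Exact inverse of :func:`apply_permutation`."""
    if len(seq) != len(p):
        raise InvalidInputError(
            f"sequence length {len(seq)} != permutation size {len(p)}")
    out = np.empty(len(seq), dtype=np.uint8)
    out[p.mapping] = seq.values()
    return NucSeq.from_values(out, seq.alphabet)


# ------------------------------------------------------------- S-box layer

def _xorshift64(c: int) -> int:
    c ^= (c << 13) & _MASK64
    c ^= c >> 7
    c ^= (c << 17) & _MASK64
    return c


@dataclass(frozen=True)
class SBoxFamily:
    """Keyed bijections over {A, C, G, U}, one per nucleotide context.

    ``base_index_fwd[c]`` selects the base S-box for context symbol c
    (A, C, G, U, start sentinel) in the forward pass; the effective box at
    each position additionally rotates by the rolling 64-bit accumulator, so
    the substitution depends on everything already processed. The whole
    family is a deterministic function of the master key.
    """

    base_index_fwd: tuple[int, ...]
    base_index_bwd: tuple[int, ...]
    acc_seed_fwd: int
    acc_seed_bwd: int
    is_identity: bool = False

    @classmethod
    def from_key(cls, key: KeyMaterial) -> "SBoxFamily":
        def idx(label: bytes, ctx: bytes) -> int:
            d = hmac.new(key.master_key, b"sbox-" + label + b":" + ctx,
                         hashlib.sha256).digest()
            return int.from_bytes(d[:5], "big") % 24

        def seed(label: bytes) -> int:
            d = hmac.new(key.master_key, b"sbox-acc-" + label,
                         hashlib.sha256).digest()
            return int.from_bytes(d[:8], "big")

        return cls(
            base_index_fwd=tuple(idx(b"fwd", c) for c in _CONTEXT_LABELS),
            base_index_bwd=tuple(idx(b"bwd", c) for c in _CONTEXT_LABELS),
            acc_seed_fwd=seed(b"fwd"),
            acc_seed_bwd=seed(b"bwd"),
        )

    @classmethod
    def identity(cls) -> "SBoxFamily":
        """All boxes the identity: transcription reduces to pure T -> U."""
        return cls((0,) * 5, (0,) * 5, 0, 0, is_identity=True)

    def boxes(self, direction: str = "fwd") -> dict[str, tuple[int, ...]]:
        """The per-context base bijections (for inspection and tests)."""
        idxs = self.base_index_fwd if direction == "fwd" else self.base_index_bwd
        return {lbl.decode(): _VALUE_PERMS[i]
                for lbl, i in zip(_CONTEXT_LABELS, idxs)}


def _chain(values: np.ndarray, base_index: tuple[int, ...], seed: int,
           reverse: bool, invert: bool) -> np.ndarray:
    """Context-chained substitution pass (the diffusion engine).

    Sequential by construction: the effective S-box at each position is
    selected by the context symbol (previous plaintext-side symbol, or the
    start sentinel) plus the rolling accumulator over all processed
    (input, output) pairs.
    """
    vals = values.tolist()
    n = len(vals)
    out = [0] * n
    c = seed
    prev = 4  # sentinel context
    order = range(n - 1, -1, -1) if reverse else range(n)
    perms, inv_perms = _VALUE_PERMS, _VALUE_PERMS_INV
    bidx = base_index
    for i in order:
        idx = (bidx[prev] + c) % 24
        if invert:
            y = vals[i]
            x = inv_perms[idx][y]
        else:
            x = vals[i]
            y = perms[idx][x]
        out[i] = x if invert else y
        c = _xorshift64(c ^ ((y * 5 + x + 1) * _GOLD & _MASK64))
        prev = x  # context = the plaintext-side symbol
    return np.asarray(out, dtype=np.uint8)


def transcribe(seq: NucSeq, sboxes: SBoxFamily) -> NucSeq:
    """DNA -> RNA: T -> U alphabet shift, then the forward chained S-box."""
    seq = as_nucseq(seq, Alphabet.DNA)
    v = seq.values()
    if not sboxes.is_identity and v.size:
        v = _chain(v, sboxes.base_index_fwd, sboxes.acc_seed_fwd,
                   reverse=False, invert=False)
    return NucSeq.from_values(v, Alphabet.RNA)


def untranscribe(seq: NucSeq, sboxes: SBoxFamily) -> NucSeq:
    """Exact inverse of :func:`transcribe`."""
    seq = as_nucseq(seq, Alphabet.RNA)
    v = seq.values()
    if not sboxes.is_identity and v.size:
        v = _chain(v, sboxes.base_index_fwd, sboxes.acc_seed_fwd,
                   reverse=False, invert=True)
    return NucSeq.from_values(v, Alphabet.DNA)


def diffuse_backward(seq: NucSeq, sboxes: SBoxFamily) -> NucSeq:
    """Reverse-direction chained S-box pass over the RNA payload.

    Applied after :func:`transcribe` so that a localized change also
    re-randomizes every *upstream* symbol (the forward pass only reaches
    downstream ones)."""
    seq = as_nucseq(seq, Alphabet.RNA)
    v = seq.values()
    if not sboxes.is_identity and v.size:
        v = _chain(v, sboxes.base_index_bwd, sboxes.acc_seed_bwd,
                   reverse=True, invert=False)
    return NucSeq.from_values(v, Alphabet.RNA)


def undiffuse_backward(seq: NucSeq, sboxes: SBoxFamily) -> NucSeq:
    """Exact inverse of :func:`diffuse_backward`."""
    seq = as_nucseq(seq, Alphabet.RNA)
    v = seq.values()
    if not sboxes.is_identity and v.size:
        v = _chain(v, sboxes.base_index_bwd, sboxes.acc_seed_bwd,
                   reverse=True, invert=True)
    return NucSeq.from_values(v, Alphabet.RNA)


# ---------------------------------------------------------------- layers

def complement(seq: NucSeq) -> NucSeq:
    """Positionwise Watson-Crick complement of a DNA sequence."""
    return as_nucseq(seq, Alphabet.DNA).complemented()


def dna_xor(seq: NucSeq, stream: np.ndarray, table: EncodingTable) -> NucSeq:
    """One-time-pad XOR in the 2-bit domain of the given encoding table.

    Self-inverse: applying the same stream twice restores the input.
    """
    seq = as_nucseq(seq, Alphabet.DNA)
    stream = np.asarray(stream, dtype=np.uint8)
    if stream.size != len(seq):
        raise InvalidInputError(
            f"stream length {stream.size} != sequence length {len(seq)}")
    return table.encode_values(table.decode_values(seq) ^ stream)


# ------------------------------------------------------------- ciphertext

@dataclass(frozen=True)
class CipherText:
    """RNA payload plus the header needed to invert every layer."""

    payload: NucSeq
    salt: bytes
    kdf_iterations: int
    stream_nonce: int
    plaintext_bit_length: int
    code_params: CodeConfig | None = None
    constraint_counters: tuple[int, ...] | None = None
    constraint_limits: "_constraints.ConstraintLimits | None" = None
    version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.payload.alphabet is not Alphabet.RNA:
            raise FormatError("ciphertext payload must use the RNA alphabet")
        if self.plaintext_bit_length < 0:
            raise FormatError("plaintext_bit_length must be non-negative")


# ----------------------------------------------------------- byte framing

def rna_to_bytes(seq: NucSeq) -> bytes:
    """Pack the canonical 2-bit values, 4 bases per byte, big-endian."""
    seq = as_nucseq(seq, Alphabet.RNA)
    if len(seq) % 4:
        raise FormatError("RNA length must be a multiple of 4 to pack bytes")
    v = seq.values()
    bits = np.empty(2 * v.size, dtype=np.uint8)
    bits[0::2] = v >> 1
    bits[1::2] = v & 1
    return np.packbits(bits).tobytes()


def bytes_to_rna(data: bytes) -> NucSeq:
    """Inverse of :func:`rna_to_bytes`."""
    bits = np.unpackbits(np.frombuffer(bytes(data), dtype=np.uint8))
    return NucSeq.from_values(bits[0::2] * 2 + bits[1::2], Alphabet.RNA)


# ---------------------------------------------------------- encrypt/decrypt

def encrypt_with_key(plaintext: bytes, key: KeyMaterial,
                     config: EncryptionConfig | None = None,
                     nonce: int = 0,
                     table_override: int | None = None) -> CipherText:
    """Encrypt under already-derived key material (see :func:`encrypt`).

    ``table_override`` forces a specific encoding-table index instead of
    the key-derived one (debugging aid; the same override must be passed
    at decryption).
    """
    config = config or EncryptionConfig()
    plaintext = bytes(plaintext)
    table = enumerate_tables()[key.table_index if table_override is None
                               else table_override]
    bits = text_to_bits(plaintext)

    if bits.size:
        dna = bits_to_dna(bits, table)
        dna = complement(dna)
        dna = dna_xor(dna, keystream(key, nonce, len(dna)), table)
        perm = Permutation(permutation_from_chaos(
            key, config.logistic, n=len(dna)))
        dna = apply_permutation(dna, perm)
        fam = SBoxFamily.from_key(key)
        rna = transcribe(dna, fam)
        rna = diffuse_backward(rna, fam)
    else:
        rna = NucSeq("", Alphabet.RNA)

    if config.ecc is not None and len(rna):
        rna = bytes_to_rna(rs_encode(rna_to_bytes(rna), config.ecc))

    ct = CipherText(
        payload=rna,
        salt=key.salt,
        kdf_iterations=key.kdf_iterations,
        stream_nonce=nonce,
        plaintext_bit_length=bits.size,
        code_params=config.ecc,
    )
    if config.constraints is not None:
        ct = _constraints.enforce(ct, key, config.constraints)
    return ct


def encrypt(plaintext: bytes, passphrase: str,
            config: EncryptionConfig | None = None, *,
            salt: bytes | None = None, nonce: int = 0) -> CipherText:
    """Full pipeline: encode, complement, XOR, permute, transcribe, diffuse,
    then the optional Reed-Solomon outer code and constraint layer.

    A fresh random salt is drawn unless one is supplied (tests and seeded
    experiments pass an explicit salt for reproducibility).
    """
    config = config or EncryptionConfig()
    if salt is None:
        salt = secrets.token_bytes(16)
    key = derive_master_key(passphrase, salt, config.kdf_iterations)
    return encrypt_with_key(plaintext, key, config, nonce=nonce)


def decrypt_with_key(ct: CipherText, key: KeyMaterial,
                     config: EncryptionConfig | None = None,
                     table_override: int | None = None) -> bytes:
    """Invert every layer under already-derived key material."""
    config = config or EncryptionConfig()
    if ct.version != FORMAT_VERSION:
        raise FormatError(f"unsupported header version {ct.version!r}")
    if ct.plaintext_bit_length % 8:
        raise FormatError("plaintext_bit_length must be a whole byte count")

    rna = ct.payload
    if ct.constraint_counters is not None:
        rna = _constraints.unmask(rna, key, ct.stream_nonce,
                                  ct.constraint_counters,
                                  ct.constraint_limits
                                  or _constraints.ConstraintLimits())
    if ct.code_params is not None and len(rna):
        rna = bytes_to_rna(rs_decode(rna_to_bytes(rna), ct.code_params))

    n_bases = ct.plaintext_bit_length // 2
    if len(rna) != n_bases:
        raise FormatError(
            f"payload length {len(rna)} bases inconsistent with header "
            f"({n_bases} expected): truncated or corrupted record")
    if n_bases == 0:
        return b""

    fam = SBoxFamily.from_key(key)
    rna = undiffuse_backward(rna, fam)
    dna = untranscribe(rna, fam)
    perm = Permutation(permutation_from_chaos(key, config.logistic,
                                              n=len(dna)))
    dna = invert_permutation(dna, perm)
    table = enumerate_tables()[key.table_index if table_override is None
                               else table_override]
    dna = dna_xor(dna, keystream(key, ct.stream_nonce, len(dna)), table)
    dna = complement(dna)
    return bits_to_bytes(dna_to_bits(dna, table))


def decrypt(ct: CipherText, passphrase: str,
            config: EncryptionConfig | None = None) -> bytes:
    """Invert the chain; exact plaintext when key and payload are intact.

    KDF cost, code parameters and constraint counters all come from the
    header; ``config`` only matters when encryption used non-default
    logistic-map parameters. No authentication tag is carried: a wrong
    passphrase yields noise (or a Reed-Solomon decoding failure), never an
    explicit verdict.
    """
    key = derive_master_key(passphrase, ct.salt, ct.kdf_iterations)
    return decrypt_with_key(ct, key, config)
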