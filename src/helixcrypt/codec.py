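"""Bytes/bits <-> DNA conversion under the 24 key-selectable encoding tables.

Each table is a bijection from the four bit pairs (00, 01, 10, 11) to the
four DNA bases. The 24 tables enumerate the 4! base permutations in
lexicographic order over the assigned base string, rotated so that the
canonical scheme (00->A, 01->T, 10->C, 11->G) sits at index 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InvalidInputError
from .nucseq import Alphabet, NucSeq, as_nucseq

#: canonical table-0 assignment for bit pairs 00, 01, 10, 11
CANONICAL_ASSIGNMENT = ("A", "T", "C", "G")


@dataclass(frozen=True)
class EncodingTable:
    """Bijection between 2-bit values and DNA bases."""

    index: int
    assignment: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if sorted(self.assignment) != ["A", "C", "G", "T"]:
            raise InvalidInputError("assignment must be a bijection onto ACGT")

    def encode_values(self, values: np.ndarray) -> NucSeq:
        """Map 2-bit values to DNA bases."""
        chars = np.frombuffer("".join(self.assignment).encode(),
                              dtype=np.uint8)
        return NucSeq(chars[np.asarray(values, dtype=np.uint8)]
                      .tobytes().decode("ascii"), Alphabet.DNA)

    def decode_values(self, seq: NucSeq | str) -> np.ndarray:
        """Map DNA bases back to their 2-bit values under this table."""
        seq = as_nucseq(seq, Alphabet.DNA)
        lut = np.zeros(256, dtype=np.uint8)
        for v, base in enumerate(self.assignment):
            lut[ord(base)] = v
        return lut[np.frombuffer(seq.seq.encode(), dtype=np.uint8)]


@lru_cache(maxsize=1)
def enumerate_tables() -> tuple[EncodingTable, ...]:
    """The 24 encoding tables in their fixed, documented order.

    Lexicographic over the base string assigned to (00, 01, 10, 11), rotated
    so the canonical assignment is index 0; all 24 are distinct.
    """
    perms = sorted(itertools.permutations("ACGT"))
    anchor = perms.index(CANONICAL_ASSIGNMENT)
    ordered = perms[anchor:] + perms[:anchor]
    return tuple(EncodingTable(i, p) for i, p in enumerate(ordered))


def text_to_bits(message: bytes) -> np.ndarray:
    """Big-endian 8-bit expansion of each byte; length = 8 * byte count."""
    if isinstance(message, str):
        message = message.encode("utf-8")
    return np.unpackbits(np.frombuffer(bytes(message), dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    """Inverse of :func:`text_to_bits` (bit count must be a multiple of 8)."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % 8:
        raise InvalidInputError("bit count must be a multiple of 8")
    return np.packbits(bits).tobytes()


def bits_to_dna(bits: np.ndarray, table: EncodingTable,
                pad: bool = False) -> NucSeq:
    """Map consecutive bit pairs through the table; length = bits / 2.

    Odd-length input is rejected unless ``pad`` is set, in which case a
    trailing 0-bit is appended (the caller must record the original bit
    length to invert exactly).
    """
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % 2:
        if not pad:
            raise InvalidInputError(
                "odd bit count; enable pad=True to append a 0-bit")
        bits = np.append(bits, np.uint8(0))
    values = bits[0::2] * 2 + bits[1::2]
    return table.encode_values(values)


def dna_to_bits(seq: NucSeq | str, table: EncodingTable) -> np.ndarray:
    """Exact inverse of :func:`bits_to_dna` for even-length bit input."""
    values = table.decode_values(seq)
    bits = np.empty(2 * values.size, dtype=np.uint8)
    bits[0::2] = values >> 1
    bits[1::2] = values & 1
    return bits
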